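# Category correspondence between the 2016 individual microdata codes, the
# unified synthetic-population codes, and the census-profile characteristic
# labels summed into each unified category.  Swap this file to target a
# different census vintage.
version: "2016"
variables:
  agegrp:
    source_to_unified:
      1: 0    # 0-4
      2: 1    # 5-6
      3: 1    # 7-9
      4: 2    # 10-11
      5: 2    # 12-14
      6: 3    # 15-17
      7: 3    # 18-19
      8: 4    # 20-24
      9: 5    # 25-29
      10: 6
      11: 7
      12: 8
      13: 9
      14: 10
      15: 11
      16: 12
      17: 13
      18: 14
      19: 15
      20: 16
      21: 17   # 85+
    ignored_source_codes: [88]   # "Not available": record dropped, count logged
    profile_labels:
      0: ["0 to 4 years"]
      1: ["5 to 9 years"]
      2: ["10 to 14 years"]
      3: ["15 to 19 years"]
      4: ["20 to 24 years"]
      5: ["25 to 29 years"]
      6: ["30 to 34 years"]
      7: ["35 to 39 years"]
      8: ["40 to 44 years"]
      9: ["45 to 49 years"]
      10: ["50 to 54 years"]
      11: ["55 to 59 years"]
      12: ["60 to 64 years"]
      13: ["65 to 69 years"]
      14: ["70 to 74 years"]
      15: ["75 to 79 years"]
      16: ["80 to 84 years"]
      17: ["85 years and over"]
  sex:
    source_to_unified:
      1: 0    # female
      2: 1    # male
    # profile counts come from the Male/Female columns of "Population, 2016"
    profile_labels: {}
  hdgree:
    source_to_unified:
      1: 0     # no certificate, diploma or degree
      2: 1     # secondary school or equivalent
      3: 2     # all postsecondary
      4: 2
      5: 2
      6: 2
      7: 2
      8: 2
      9: 2
      10: 2
      11: 2
      12: 2
      13: 2
      88: 0    # not available
      99: 0    # not applicable (<15 y/o)
    under15_to: 0   # profile rows cover 15+ only; 0-14 added to this category
    profile_labels:
      0: ["No certificate, diploma or degree"]
      1: ["Secondary (high) school diploma or equivalency certificate"]
      2: ["Postsecondary certificate, diploma or degree"]
  lfact:
    source_to_unified:
      1: 0     # employed
      2: 0
      3: 1     # unemployed
      4: 1
      5: 1
      6: 1
      7: 1
      8: 1
      9: 1
      10: 1
      11: 2    # not in labour force
      12: 2
      13: 2
      14: 2
      99: 2    # not applicable (<15 y/o)
    under15_to: 2
    profile_labels:
      0: ["Employed"]
      1: ["Unemployed"]
      2: ["Not in the labour force"]
  hhsize:
    source_to_unified:
      8: 0     # not available -> 1 person
      1: 0
      2: 1
      3: 2
      4: 3
      5: 4
      6: 4     # 6 persons -> 5 or more
      7: 4     # 7 persons or more -> 5 or more
    profile_labels:
      0: ["1 person"]
      1: ["2 persons"]
      2: ["3 persons"]
      3: ["4 persons"]
      4: ["5 or more persons"]
  totinc:
    # microdata carries a dollar amount, banded in code; sentinels below
    sentinel_codes: [88888888, 99999999]
    band_edges: [20000, 60000, 100000]
    under15_to: 0
    profile_labels:
      0: ["Under $10,000 (including loss)", "$10,000 to $19,999"]
      1: ["$20,000 to $29,999", "$30,000 to $39,999", "$40,000 to $49,999", "$50,000 to $59,999"]
      2: ["$60,000 to $69,999", "$70,000 to $79,999", "$80,000 to $89,999", "$90,000 to $99,999"]
      3: ["$100,000 and over"]
  prihm:
    source_to_unified:
      0: 0
      1: 1
    profile_labels: {}
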