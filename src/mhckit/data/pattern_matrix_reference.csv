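item,subscale,F1,F2,F3,F4,F5
Q01,lack_of_vigor,,0.86,,,
Q02,lack_of_vigor,,0.88,,,
Q03,lack_of_vigor,,0.91,,,
Q04,irritability,,,0.86,,
Q05,irritability,,,0.87,,
Q06,irritability,,,0.70,,
Q07,fatigue,,,,0.81,
Q08,fatigue,,,,0.84,
Q09,fatigue,,,,0.52,
Q10,anxiety,0.36,,,,
Q11,anxiety,0.74,,,,
Q12,anxiety,0.65,,,,
Q13,depressed_mood,0.71,,,,
Q14,depressed_mood,0.42,,,,
Q15,depressed_mood,0.57,,,,
Q16,depressed_mood,0.69,,,,
Q17,depressed_mood,0.62,,,,
Q18,depressed_mood,0.59,,,,
Q19,somatic,,,,,0.34
Q20,somatic,,,,,0.41
Q21,somatic,,,,,0.52
Q22,somatic,,,,,0.60
Q23,somatic,,,,,0.54
Q24,somatic,,,,,0.50
Q25,somatic,,,,,0.34
Q26,somatic,,,,,0.32
Q27,somatic,0.32,,,,
Q28,somatic,,,,,0.32
Q29,somatic,0.29,,,,
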