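population,longitude,latitude
NBCI,-65.59,46.15
NBCR,-65.93,46.32
NBOP,-66.66,45.96
NBPH,-65.30,45.79
MASB,-73.29,42.26
MEBP,-68.64,45.67
MEEB,-69.16,44.79
NHDF,-71.26,43.11
NYCM,-74.17,41.95
NSDL,-64.41,44.50
NSRL,-65.14,44.27
NSMB,-63.87,44.64
NSUM,-63.61,44.95
MNBL,-93.13,45.33
ONCL,-94.27,49.08
ONFR,-80.28,46.05
ONGR,-84.22,46.75
ONHF,-78.08,44.60
ONML,-79.66,45.02
ONMF,-81.72,46.09
ONRC,-77.40,45.66
ONTO,-79.48,47.13
ONWL,-80.65,46.84
PQCT,-70.80,47.08
PQLP,-75.91,45.56
PQSR,-71.01,46.01
PQSS,-72.29,46.64
VASB,-80.02,37.38
NCAV,-82.53,35.62
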