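id,volume_cc,coverage_pct_manual,coverage_pct_auto,si_manual,si_auto,ci_rtog_manual,ci_rtog_auto,ci_paddick_manual,ci_paddick_auto
1026002,6.7,96,96,0.9,0.76,1.07,1.26,0.86,0.73
1026003,1.5,96,98,0.86,0.8,1.12,1.23,0.83,0.78
1026004,0.3,96,96,0.8,0.79,1.20,1.22,0.77,0.76
1026006,0.9,96,98,0.85,0.75,1.13,1.31,0.82,0.74
1026007,2.9,96,98,0.86,0.8,1.12,1.23,0.83,0.78
1026009,3.7,95,95,0.78,0.84,1.22,1.13,0.74,0.80
1026010,1.5,99,96,0.85,0.77,1.16,1.25,0.84,0.74
1026011,3.7,98,94,0.85,0.87,1.15,1.08,0.83,0.82
1026012,2.2,95,97,0.84,0.79,1.13,1.23,0.80,0.77
1026021,3.4,95,94,0.83,0.88,1.14,1.07,0.79,0.83
1026031,0.4,96,97,0.83,0.76,1.16,1.28,0.80,0.74
1026032,1.7,99,95,0.81,0.88,1.22,1.08,0.80,0.84
1026034,2.9,95,95,0.9,0.86,1.06,1.10,0.86,0.82
1026035,0.7,95,93,0.82,0.83,1.16,1.12,0.78,0.77
1026037,2.5,95,95,0.88,0.81,1.08,1.17,0.84,0.77
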