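compound_id,xgb_active,xgb_inactive,xgb_percent,xgb_inconsistent,rf_active,rf_inactive,rf_percent,rf_inconsistent
10,105,14,88.2,,98,21,82.4,
22,113,21,84.3,,99,35,73.9,
34,86,22,79.6,,88,20,81.5,
49,76,20,79.2,,73,23,76.0,
54,60,29,67.4,,57,32,64.0,
66,76,20,79.2,,75,21,78.1,
72,98,23,81.0,,87,34,71.9,
78,77,2,97.5,,65,14,82.3,
107,54,17,76.1,,58,13,81.7,
113,57,6,90.5,,56,7,88.9,
115,90,2,97.9,1,73,19,79.3,
116,67,22,75.3,,65,24,73.0,
126,97,2,98.0,,80,19,80.8,
127,66,1,98.5,,55,12,82.1,
133,51,2,96.2,,41,12,77.4,
135,65,0,100,,56,9,86.2,
146,82,5,94.3,,73,14,83.9,
148,54,3,94.7,,45,12,78.9,
156,90,7,92.8,,85,12,87.6,
162,62,5,92.5,,59,8,88.1,
250,10,32,23.8,,24,18,57.1,
312,0,1,0,,1,0,100,
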