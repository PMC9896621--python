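compound_id,nci_code,captured_by,xgb_active,xgb_inactive,xgb_percent,xgb_inconsistent,rf_active,rf_inactive,rf_percent,rf_inconsistent
317,3590,"1,2",183,31,85.5,,78,30,72.2,
318,20261,1,40,77,34.2,,ND,ND,ND,
319,59407,1,205,34,85.8,,ND,ND,ND,
320,65832,1,65,56,53.7,,ND,ND,ND,
321,745104,"1,2",3,3,50.0,,5,1,33.3,1
322,72868,1,56,45,55.4,,ND,ND,ND,
323,77028,1,52,64,44.8,,ND,ND,ND,
324,77029,1,47,64,42.3,,ND,ND,ND,
325,82523,1,152,20,88.4,,ND,ND,ND,
326,98711,1,48,71,40.3,,ND,ND,ND,
327,100791,1,70,38,64.8,,ND,ND,ND,
328,107137,1,102,41,71.3,,ND,ND,ND,
329,107139,2,ND,ND,ND,,45,11,80.4,
330,267431,"1,2",40,48,45.5,,48,37,56.5,
331,289523,1,76,28,73.1,,ND,ND,ND,
332,338310,2,ND,ND,ND,,129,34,79.1,
333,341076,"1,2",217,39,84.8,,189,29,86.7,
334,341077,"1,2",209,41,83.6,,180,37,82.9,
335,363007,2,ND,ND,ND,,119,42,73.9,
336,372667,"1,2",158,26,85.9,,131,40,76.6,
337,373233,1,53,55,49.1,,ND,ND,ND,
338,380962,1,45,33,57.7,,ND,ND,ND,
339,645793,2,ND,ND,ND,,40,23,63.5,
340,651016,2,ND,ND,ND,,52,33,61.2,
341,669269,"1,2",135,54,71.4,,124,33,79.0,
342,722969,2,ND,ND,ND,,51,20,71.8,
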