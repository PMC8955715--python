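clcr,weight_kg,loading_dose_g,md_dose_g,md_times_per_day,auc_24_48
100,80,2.0,1.25,2,512
100,70,2.0,1.25,2,512
100,60,1.75,1.25,2,504
90,80,2.0,1.0,2,465
90,70,2.0,1.0,2,465
90,60,1.75,1.0,2,456
90,50,1.5,1.0,2,446
80,80,1.75,1.0,2,496
80,70,1.75,1.0,2,496
80,60,1.75,1.0,2,496
80,50,1.5,1.0,2,494
70,80,1.75,0.75,2,449
70,70,1.75,0.75,2,449
70,60,1.75,0.75,2,449
70,50,1.5,0.75,2,435
70,40,1.25,0.75,2,420
60,80,1.75,0.75,2,511
60,70,1.75,0.75,2,511
60,60,1.75,0.75,2,511
60,50,1.5,0.75,2,492
60,40,1.25,0.75,2,474
50,80,1.75,0.5,2,446
50,70,1.75,0.5,2,446
50,60,1.75,0.5,2,446
50,50,1.5,0.5,2,423
50,40,1.25,0.5,2,400
40,80,1.75,0.5,2,528
40,70,1.5,0.5,2,497
40,60,1.5,0.5,2,497
40,50,1.5,0.5,2,497
40,40,1.25,0.5,2,467
30,80,1.75,0.75,1,512
30,70,1.5,0.75,1,472
30,60,1.5,0.75,1,472
30,50,1.5,0.75,1,472
30,40,1.25,0.75,1,432
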