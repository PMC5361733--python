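# Per-condition focus-count summaries: mean foci/cell, SEM, number of cells,
# for each cell line x passage x marker x treatment x cell-cycle phase.
# passage: na (primary fibroblasts), low, high. treatment: control or 1Gy
# (counted 0.5 h after irradiation). phase: G1 (EdU-negative), SG2 (EdU-positive).
line_id,passage,marker,treatment,phase,mean_foci,sem,n_cells
hDF,na,gH2AX,control,G1,1.13,0.11,463
hDF,na,gH2AX,control,SG2,29.9,1.3,260
hDF,na,gH2AX,1Gy,G1,19.89,0.36,485
hDF,na,gH2AX,1Gy,SG2,45.49,0.88,97
hDF,na,53BP1,control,G1,1.49,0.07,486
hDF,na,53BP1,control,SG2,19.64,1.2,380
hDF,na,53BP1,1Gy,G1,15.55,0.22,501
hDF,na,53BP1,1Gy,SG2,19.20,0.91,69
CBIA-3,low,gH2AX,control,G1,5.56,0.22,464
CBIA-3,low,gH2AX,control,SG2,22.98,0.38,523
CBIA-3,low,gH2AX,1Gy,G1,21.87,0.34,612
CBIA-3,low,gH2AX,1Gy,SG2,28.71,0.34,554
CBIA-3,low,53BP1,control,G1,2.13,0.12,445
CBIA-3,low,53BP1,control,SG2,8.76,0.35,407
CBIA-3,low,53BP1,1Gy,G1,19.01,0.31,552
CBIA-3,low,53BP1,1Gy,SG2,23.1,0.42,496
CBIA-3,high,gH2AX,control,G1,4.42,0.20,483
CBIA-3,high,gH2AX,control,SG2,17.91,0.41,337
CBIA-3,high,gH2AX,1Gy,G1,8.01,0.27,594
CBIA-3,high,gH2AX,1Gy,SG2,7.97,0.35,480
CBIA-3,high,53BP1,control,G1,1.46,0.07,625
CBIA-3,high,53BP1,control,SG2,4.73,0.18,510
CBIA-3,high,53BP1,1Gy,G1,14.45,0.29,551
CBIA-3,high,53BP1,1Gy,SG2,13.66,0.31,447
CBIA-5,low,gH2AX,control,G1,5.69,0.23,542
CBIA-5,low,gH2AX,control,SG2,25.1,0.47,415
CBIA-5,low,gH2AX,1Gy,G1,28.6,0.52,437
CBIA-5,low,gH2AX,1Gy,SG2,41.00,0.55,421
CBIA-5,low,53BP1,control,G1,4.03,0.18,445
CBIA-5,low,53BP1,control,SG2,15.3,0.49,425
CBIA-5,low,53BP1,1Gy,G1,17.84,0.26,613
CBIA-5,low,53BP1,1Gy,SG2,23.32,0.30,642
CBIA-5,high,gH2AX,control,G1,2.98,0.13,520
CBIA-5,high,gH2AX,control,SG2,10.98,0.26,508
CBIA-5,high,gH2AX,1Gy,G1,11.57,0.27,445
CBIA-5,high,gH2AX,1Gy,SG2,24.45,0.39,480
CBIA-5,high,53BP1,control,G1,1.56,0.07,608
CBIA-5,high,53BP1,control,SG2,4.71,0.21,461
CBIA-5,high,53BP1,1Gy,G1,8.04,0.17,490
CBIA-5,high,53BP1,1Gy,SG2,10.84,0.20,514
CBIA-7,low,gH2AX,control,G1,5.89,0.25,382
CBIA-7,low,gH2AX,control,SG2,23.77,0.45,414
CBIA-7,low,gH2AX,1Gy,G1,26.48,0.44,511
CBIA-7,low,gH2AX,1Gy,SG2,36.71,0.52,444
CBIA-7,low,53BP1,control,G1,2.73,0.13,487
CBIA-7,low,53BP1,control,SG2,10.42,0.31,421
CBIA-7,low,53BP1,1Gy,G1,20.05,0.35,591
CBIA-7,low,53BP1,1Gy,SG2,21.94,0.38,560
CBIA-7,high,gH2AX,control,G1,2.56,0.13,547
CBIA-7,high,gH2AX,control,SG2,11.78,0.25,534
CBIA-7,high,gH2AX,1Gy,G1,12.41,0.26,580
CBIA-7,high,gH2AX,1Gy,SG2,12.73,0.30,452
CBIA-7,high,53BP1,control,G1,1.51,0.07,586
CBIA-7,high,53BP1,control,SG2,6.5,0.27,415
CBIA-7,high,53BP1,1Gy,G1,16.9,0.32,556
CBIA-7,high,53BP1,1Gy,SG2,17.62,0.34,415
CCTL-14,low,gH2AX,control,G1,4.45,0.20,554
CCTL-14,low,gH2AX,control,SG2,12.83,0.31,544
CCTL-14,low,gH2AX,1Gy,G1,20.99,0.34,634
CCTL-14,low,gH2AX,1Gy,SG2,30.37,0.57,378
CCTL-14,low,53BP1,control,G1,2.73,0.14,629
CCTL-14,low,53BP1,control,SG2,10.28,0.36,508
CCTL-14,low,53BP1,1Gy,G1,16.77,0.27,681
CCTL-14,low,53BP1,1Gy,SG2,19.13,0.39,452
CCTL-14,high,gH2AX,control,G1,6.66,0.29,510
CCTL-14,high,gH2AX,control,SG2,19.30,0.49,427
CCTL-14,high,gH2AX,1Gy,G1,16.26,0.28,642
CCTL-14,high,gH2AX,1Gy,SG2,19.38,0.34,423
CCTL-14,high,53BP1,control,G1,4.75,0.21,576
CCTL-14,high,53BP1,control,SG2,14.34,0.52,402
CCTL-14,high,53BP1,1Gy,G1,21.49,0.30,653
CCTL-14,high,53BP1,1Gy,SG2,24.20,0.42,425
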