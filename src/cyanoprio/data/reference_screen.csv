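fraction_id,cell_model,mean_viability,sd_viability,n,role,published_group
LEGE 16572_C,3D_HCT116,57.54,20.74,3,test,A
LEGE 16572_C,2D_HCT116,21.30,8.79,3,test,A
LEGE 16572_C,2D_hCMEC/D3,12.97,5.14,3,test,A
LEGE 17548_C,3D_HCT116,58.05,11.10,3,test,A
LEGE 17548_C,2D_HCT116,16.33,8.50,3,test,A
LEGE 17548_C,2D_hCMEC/D3,16.67,11.84,3,test,A
LEGE 17548_D,3D_HCT116,58.74,13.40,3,test,A
LEGE 17548_D,2D_HCT116,27.08,17.23,3,test,A
LEGE 17548_D,2D_hCMEC/D3,36.52,16.23,3,test,A
LEGE 15488_C,3D_HCT116,65.16,10.30,3,test,A
LEGE 15488_C,2D_HCT116,25.69,21.02,3,test,A
LEGE 15488_C,2D_hCMEC/D3,14.51,8.65,3,test,A
LEGE 181150_D,3D_HCT116,75.95,4.25,3,test,A
LEGE 181150_D,2D_HCT116,16.40,3.26,3,test,A
LEGE 181150_D,2D_hCMEC/D3,13.80,3.14,3,test,A
LEGE 05292_C,3D_HCT116,68.32,4.60,3,positive_control,A
LEGE 05292_C,2D_HCT116,9.13,2.64,3,positive_control,A
LEGE 05292_C,2D_hCMEC/D3,12.83,3.35,3,positive_control,A
LEGE XX358_D,3D_HCT116,72.28,16.86,3,test,B
LEGE XX358_D,2D_HCT116,50.11,20.43,3,test,B
LEGE XX358_D,2D_hCMEC/D3,44.60,14.66,3,test,B
LEGE 16572_D,3D_HCT116,72.34,6.05,3,test,B
LEGE 16572_D,2D_HCT116,58.15,23.40,3,test,B
LEGE 16572_D,2D_hCMEC/D3,56.18,19.94,3,test,B
JM1 Amb_D,3D_HCT116,75.25,7.14,3,test,B
JM1 Amb_D,2D_HCT116,55.30,3.11,3,test,B
JM1 Amb_D,2D_hCMEC/D3,22.77,5.59,3,test,B
LEGE 15546_D,3D_HCT116,78.51,7.16,3,test,B
LEGE 15546_D,2D_HCT116,58.44,18.34,3,test,B
LEGE 15546_D,2D_hCMEC/D3,59.17,15.65,3,test,B
LEGE 16502_E,3D_HCT116,81.53,13.30,3,test,B
LEGE 16502_E,2D_HCT116,71.38,13.24,3,test,B
LEGE 16502_E,2D_hCMEC/D3,58.29,7.41,3,test,B
JM1 Amb_E,3D_HCT116,82.07,3.02,3,test,B
JM1 Amb_E,2D_HCT116,56.16,12.80,3,test,B
JM1 Amb_E,2D_hCMEC/D3,21.15,5.76,3,test,B
JM5_amb_D,3D_HCT116,90.07,1.24,3,test,C
JM5_amb_D,2D_HCT116,52.49,5.34,3,test,C
JM5_amb_D,2D_hCMEC/D3,31.85,4.39,3,test,C
JM5_amb_E,3D_HCT116,94.92,5.66,3,test,C
JM5_amb_E,2D_HCT116,48.11,12.12,3,test,C
JM5_amb_E,2D_hCMEC/D3,55.44,7.66,3,test,C
LEGE 06078_D,3D_HCT116,99.29,7.89,3,test,C
LEGE 06078_D,2D_HCT116,46.51,12.42,3,test,C
LEGE 06078_D,2D_hCMEC/D3,69.21,15.63,3,test,C
LEGE 07092_D,3D_HCT116,94.96,6.94,3,test,C
LEGE 07092_D,2D_HCT116,47.77,3.62,3,test,C
LEGE 07092_D,2D_hCMEC/D3,55.86,3.63,3,test,C
LEGE 07167_C,3D_HCT116,85.76,2.54,3,test,C
LEGE 07167_C,2D_HCT116,25.86,1.36,3,test,C
LEGE 07167_C,2D_hCMEC/D3,56.83,4.00,3,test,C
LEGE 07167_D,3D_HCT116,82.74,3.25,3,test,C
LEGE 07167_D,2D_HCT116,49.51,1.90,3,test,C
LEGE 07167_D,2D_hCMEC/D3,10.93,2.87,3,test,C
LEGE 07167_E,3D_HCT116,99.70,4.71,3,test,C
LEGE 07167_E,2D_HCT116,47.34,1.59,3,test,C
LEGE 07167_E,2D_hCMEC/D3,53.96,3.48,3,test,C
LEGE 08333_D,3D_HCT116,106.90,5.38,3,test,C
LEGE 08333_D,2D_HCT116,85.02,1.57,3,test,C
LEGE 08333_D,2D_hCMEC/D3,80.56,5.12,3,test,C
LEGE 15488_D,3D_HCT116,99.09,4.96,3,test,C
LEGE 15488_D,2D_HCT116,36.76,23.26,3,test,C
LEGE 15488_D,2D_hCMEC/D3,20.17,15.65,3,test,C
LEGE 181148_E,3D_HCT116,93.04,6.94,3,test,C
LEGE 181148_E,2D_HCT116,64.14,14.46,3,test,C
LEGE 181148_E,2D_hCMEC/D3,48.58,4.75,3,test,C
LEGE 181148_F,3D_HCT116,93.49,6.54,3,test,C
LEGE 181148_F,2D_HCT116,71.52,20.38,3,test,C
LEGE 181148_F,2D_hCMEC/D3,48.44,2.02,3,test,C
LEGE 181149_D,3D_HCT116,94.01,7.29,3,test,C
LEGE 181149_D,2D_HCT116,64.47,22.29,3,test,C
LEGE 181149_D,2D_hCMEC/D3,40.25,2.66,3,test,C
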