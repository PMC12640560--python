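patient_code,age,sex,ecog_laterality_mm,n_monopolar,n_bipolar,lead_name,lead_type,tip_x_mm,tip_y_mm,tip_z_mm
P01,62,M,34.0,14,22,MDT3389,standard,12.1,-4.9,-3.5
P02,53,M,40.9,14,28,MDT3389,standard,8.8,-1.1,-4.6
P03,57,M,24.3,14,25,MDT3389,standard,10.8,-3.9,-2.8
P04,44,M,18.9,33,9,ABT6172,steerable,9.8,-4.9,-5.9
P05,53,M,28.0,39,10,BSC2202,steerable,10.7,-2.5,-6.6
P06,60,M,26.5,34,6,ABT6172,steerable,-12.7,-2.3,-4.2
P07,64,M,35.0,0,18,MDT3389,standard,13.1,-5.4,-6.1
P08,65,M,44.0,14,20,MDT3389,standard,13.4,-1.3,-4.1
P09,60,M,41.5,0,18,MDT3387,standard,12.7,-2.4,-4.0
P10,69,M,27.5,9,18,BSC2201,standard,9.3,-4.8,-7.3
P11,67,M,22.6,0,15,MDT3387,standard,10.9,-1.6,-4.6
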