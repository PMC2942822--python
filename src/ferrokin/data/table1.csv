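diet,param,best_fit,lower,upper
deficient,kp_bon,13.22,12.47,13.63
deficient,kp_kid,0.42,0.28,0.54
deficient,kp_int,0.98,0.77,1.06
deficient,kp_liv,2.27,1.83,2.54
deficient,kp_sto,0.09,0.06,0.18
deficient,kp_intg,1.04,0.89,1.32
deficient,kp_fat,0.04,0.03,0.05
deficient,kp_mus,0.96,0.8,1.23
deficient,kp_lun,0.79,0.64,1.06
deficient,kp_duo,0.02,0.01,0.15
deficient,kp_bra,0.03,0.03,0.03
deficient,kp_hea,0.11,0.1,0.14
deficient,kp_tes,0.04,0.04,0.05
deficient,kkid_p,0.2,0.11,0.32
deficient,kliv_p,0.25,0.21,0.32
deficient,ksto_out,0.18,0.09,1.72
deficient,kfat_p,0.1,0.06,0.19
deficient,kmus_p,0.03,0.02,0.05
deficient,klun_p,0.41,0.37,0.52
deficient,kbra_p,0.02,0.02,0.03
deficient,khea_p,0.06,0.03,0.08
deficient,ktes_p,0.05,0.03,0.07
deficient,kspl_p,14.61,13.86,15
deficient,kintg_out,0.03,0.02,0.05
deficient,kint_out,0.3,0.22,0.4
deficient,kduo_p,0.17,0.12,2.55
deficient,kbon_rbc,1.85,1.74,1.92
deficient,kbon_spl,0.56,0.4,0.83
deficient,krbc_spl,0.03,0.02,0.04
adequate,kp_bon,12.67,12.01,13.26
adequate,kp_kid,0.45,0.36,0.51
adequate,kp_int,0.9,0.63,1.1
adequate,kp_liv,2.61,2.28,2.9
adequate,kp_sto,0.12,0.08,0.17
adequate,kp_intg,1.14,0.96,1.35
adequate,kp_fat,0.05,0.04,0.05
adequate,kp_mus,1.49,1.31,1.8
adequate,kp_lun,0.31,0.22,0.44
adequate,kp_duo,0.04,0.03,0.06
adequate,kp_bra,0.03,0.03,0.04
adequate,kp_hea,0.13,0.12,0.15
adequate,kp_tes,0.06,0.05,0.06
adequate,kkid_p,0.2,0.14,0.25
adequate,kliv_p,0.14,0.11,0.16
adequate,ksto_out,0.37,0.27,0.49
adequate,kfat_p,0.13,0.1,0.15
adequate,kmus_p,0.15,0.12,0.21
adequate,klun_p,0.19,0.11,0.3
adequate,kbra_p,0.06,0.05,0.07
adequate,khea_p,0.08,0.06,0.09
adequate,ktes_p,0.09,0.07,0.12
adequate,kspl_p,7.29,5.53,9.15
adequate,kintg_out,0.04,0.03,0.06
adequate,kint_out,0.36,0.26,0.42
adequate,kduo_p,0.42,0.32,0.55
adequate,kbon_rbc,1.07,0.93,1.26
adequate,kbon_spl,0.1,0.08,0.13
adequate,krbc_spl,0.06,0.05,0.07
loaded,kp_bon,6.92,6.01,7.09
loaded,kp_kid,1.62,1.18,1.82
loaded,kp_int,0.93,0.66,1.01
loaded,kp_liv,5.25,4.25,5.73
loaded,kp_sto,0.27,0.21,0.37
loaded,kp_intg,1.33,1.05,1.5
loaded,kp_fat,0.066,0.051,0.075
loaded,kp_mus,2.52,2.06,2.75
loaded,kp_lun,0.63,0.56,0.75
loaded,kp_duo,0.038,0.027,0.05
loaded,kp_bra,0.021,0.019,0.022
loaded,kp_hea,0.36,0.31,0.38
loaded,kp_tes,0.043,0.037,2.68
loaded,kkid_p,0.23,0.16,0.32
loaded,kliv_p,0.1,0.073,0.12
loaded,ksto_out,0.29,0.2,0.4
loaded,kfat_p,0.099,0.079,0.12
loaded,kmus_p,0.14,0.11,0.17
loaded,klun_p,0.086,0.065,0.12
loaded,kbra_p,0.028,0.022,0.034
loaded,khea_p,0.17,0.14,0.19
loaded,ktes_p,0.067,0.044,7.16
loaded,kspl_p,1.91,1.52,2.33
loaded,kintg_out,0.072,0.057,0.102
loaded,kint_out,0.22,0.16,0.26
loaded,kduo_p,0.24,0.18,0.34
loaded,kbon_rbc,0.5,0.48,0.57
loaded,kbon_spl,0.046,0.033,0.058
loaded,krbc_spl,0.032,0.027,0.047
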