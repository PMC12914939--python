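# Published per-trial treatment-effect estimates of the seven Dep-GP primary-care
# depression trials, transcribed from the trials' joint estimand-comparison report.
# B = baseline-adjusted mean difference (follow-up score, intervention - control);
# g = Hedge's-g standardised mean difference; OR = odds ratio of improvement.
# CIs are 95%. Lower scores = improvement, so negative B/g favours intervention.
trial_id,method,B,B_ci_low,B_ci_high,g,OR,OR_ci_low,OR_ci_high
COBALT,ITT,-5.68,-7.95,-3.41,-0.42,3.30,2.12,5.13
COBALT,PP,-7.47,-9.91,-5.03,-0.56,3.76,2.32,6.08
COBALT,CACE,-8.53,-12.13,-4.93,-0.64,6.64,4.01,11.02
GENPOD,ITT,-1.19,-2.90,0.52,-0.11,1.06,0.70,1.61
GENPOD,PP,-1.08,-3.00,0.85,-0.10,1.11,0.70,1.77
GENPOD,CACE,-1.08,-3.22,1.06,-0.10,1.17,0.77,1.79
HEALTHLINES,ITT,-0.51,-1.52,0.49,-0.08,1.23,0.85,1.78
HEALTHLINES,PP,-0.87,-1.95,0.21,-0.14,1.40,0.95,2.08
HEALTHLINES,CACE,-0.61,-1.98,0.77,-0.10,1.29,0.89,1.90
IPCRESS,ITT,-7.04,-10.05,-4.03,-0.57,2.43,1.24,4.78
IPCRESS,PP,-7.47,-10.87,-4.08,-0.60,2.85,1.37,5.96
IPCRESS,CACE,-11.41,-16.43,-6.39,-0.92,2.75,1.42,5.31
MIR,ITT,-1.86,-3.95,0.23,-0.15,1.43,0.96,2.12
MIR,PP,-2.25,-4.67,0.16,-0.18,1.55,0.99,2.42
MIR,CACE,-2.55,-5.41,0.32,-0.20,1.69,0.98,2.94
PANDA,ITT,-0.51,-1.33,0.31,-0.09,1.24,0.84,1.82
PANDA,PP,-0.63,-1.47,0.21,-0.11,1.28,0.85,1.92
PANDA,CACE,-0.66,-1.53,0.21,-0.11,1.28,0.84,1.93
TREAD,ITT,-0.54,-3.06,1.98,-0.04,0.67,0.40,1.12
TREAD,PP,0.07,-2.90,3.04,0.01,0.68,0.37,1.24
TREAD,CACE,-1.16,-5.58,3.25,-0.09,0.71,0.39,1.27
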