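# Trial-level characteristics of the seven Dep-GP primary-care depression trials
# (published descriptive table). Compliers are intervention-arm participants who
# adhered to the trial's protocol; adherence_missing_n counts intervention-arm
# participants with missing adherence information. followup_n is the number of
# participants with an observed follow-up outcome (both arms). Binary outcome
# counts are no-improvement/improvement at follow-up per the trial's own
# dichotomisation. Follow-up score means/SDs are on the trial's instrument.
trial_id,intervention_type,outcome_scale,duration_weeks,n_control,n_intervention,n_compliers,adherence_missing_n,followup_n,ctrl_noresp,ctrl_resp,int_noresp,int_resp,ctrl_fu_mean,ctrl_fu_sd,int_fu_mean,int_fu_sd,ctrl_base_mean,ctrl_base_sd,int_base_mean,int_base_sd
COBALT,CBT,BDI,26,235,234,144,0,419,167,46,111,95,24.51,13,18.94,14,31.83,11,31.76,10
GENPOD,antidepressant,BDI,6,303,298,239,0,546,211,61,214,60,19.58,11,18.87,11,33.41,10,33.94,9
HEALTHLINES,telehealth,PHQ9,17,302,307,218,6,516,175,86,160,95,11.89,6,11.56,6,16.68,5,17.06,5
IPCRESS,CBT,BDI,17,147,148,90,0,206,73,21,70,42,22.09,13,14.51,11,33.46,9,32.87,8
MIR,antidepressant,BDI,12,239,241,151,32,431,139,78,119,95,19.69,12,17.97,12,30.64,10,31.48,10
PANDA,antidepressant,PHQ9,6,329,323,241,66,551,121,164,97,169,8.75,6,7.98,6,12.20,6,11.76,6
TREAD,physical_activity,BDI,17,179,182,103,0,288,94,52,102,40,16.87,13,16.12,11,32.07,10,32.05,9
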