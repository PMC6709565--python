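care_area,metric,count
NICU,total_infusion_starts,30527
NICU,total_alarms,113277
NICU,callback,22396
NICU,drive_engage_failure,5629
NICU,end_of_infusion,4650
NICU,near_end_of_infusion,10695
NICU,occlusion_downstream,62944
NICU,syringe_disengaged,6738
NICU,end_of_syringe,225
GICU,total_infusion_starts,45756
GICU,total_alarms,199482
GICU,flow_error,0
GICU,air_accumulation,6700
GICU,air_single_bubble,12724
GICU,callback,68037
GICU,door_open,14
GICU,drive_engage_failure,175
GICU,end_of_infusion,849
GICU,near_end_of_infusion,49517
GICU,occlusion_downstream,49444
GICU,occlusion_upstream,11710
GICU,syringe_disengaged,290
GICU,end_of_syringe,22
CICU,total_infusion_starts,110254
CICU,total_alarms,146694
CICU,flow_error,0
CICU,air_accumulation,275
CICU,air_single_bubble,4376
CICU,callback,42740
CICU,door_open,0
CICU,drive_engage_failure,4624
CICU,end_of_infusion,13995
CICU,near_end_of_infusion,45668
CICU,occlusion_downstream,21314
CICU,occlusion_upstream,2892
CICU,syringe_disengaged,7915
CICU,end_of_syringe,2895
PICU,total_infusion_starts,904
PICU,total_alarms,7784
PICU,callback,1581
PICU,drive_engage_failure,422
PICU,end_of_infusion,1268
PICU,near_end_of_infusion,1356
PICU,occlusion_downstream,2446
PICU,syringe_disengaged,457
PICU,end_of_syringe,254
ALL_CRITICAL_CARE,total_infusion_starts,187441
ALL_CRITICAL_CARE,total_alarms,467437
ALL_CRITICAL_CARE,flow_error,0
ALL_CRITICAL_CARE,air_accumulation,6975
ALL_CRITICAL_CARE,air_single_bubble,17100
ALL_CRITICAL_CARE,callback,134754
ALL_CRITICAL_CARE,door_open,14
ALL_CRITICAL_CARE,drive_engage_failure,10850
ALL_CRITICAL_CARE,end_of_infusion,20762
ALL_CRITICAL_CARE,near_end_of_infusion,107236
ALL_CRITICAL_CARE,occlusion_downstream,136148
ALL_CRITICAL_CARE,occlusion_upstream,14602
ALL_CRITICAL_CARE,syringe_disengaged,15400
ALL_CRITICAL_CARE,end_of_syringe,3396
WHOLE_HOSPITAL,total_infusion_starts,1600832
WHOLE_HOSPITAL,total_alarms,2211457
WHOLE_HOSPITAL,flow_error,0
WHOLE_HOSPITAL,air_accumulation,27583
WHOLE_HOSPITAL,air_single_bubble,108701
WHOLE_HOSPITAL,callback,802691
WHOLE_HOSPITAL,door_open,2710
WHOLE_HOSPITAL,drive_engage_failure,13807
WHOLE_HOSPITAL,end_of_infusion,23903
WHOLE_HOSPITAL,near_end_of_infusion,278969
WHOLE_HOSPITAL,occlusion_downstream,847438
WHOLE_HOSPITAL,occlusion_upstream,86592
WHOLE_HOSPITAL,syringe_disengaged,15288
WHOLE_HOSPITAL,end_of_syringe,3775
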