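drug,metric,count
DOBUTAMINE,infusion_starts,2509
DOBUTAMINE,callback,2776
DOBUTAMINE,drive_engage_failure,25
DOBUTAMINE,end_of_infusion,38
DOBUTAMINE,near_end_of_infusion,342
DOBUTAMINE,occlusion_downstream,267
DOBUTAMINE,syringe_disengaged,29
DOBUTAMINE,end_of_syringe,3
DOPAMINE,infusion_starts,96
DOPAMINE,callback,15
DOPAMINE,drive_engage_failure,19
DOPAMINE,end_of_infusion,13
DOPAMINE,near_end_of_infusion,1
DOPAMINE,occlusion_downstream,114
DOPAMINE,syringe_disengaged,21
DOPAMINE,end_of_syringe,2
ADRENALINE,infusion_starts,58
ADRENALINE,callback,28
ADRENALINE,drive_engage_failure,0
ADRENALINE,end_of_infusion,1
ADRENALINE,near_end_of_infusion,19
ADRENALINE,occlusion_downstream,12
ADRENALINE,syringe_disengaged,0
ADRENALINE,end_of_syringe,0
NORADRENALINE,infusion_starts,960
NORADRENALINE,callback,459
NORADRENALINE,drive_engage_failure,13
NORADRENALINE,end_of_infusion,4
NORADRENALINE,near_end_of_infusion,92
NORADRENALINE,occlusion_downstream,120
NORADRENALINE,syringe_disengaged,28
NORADRENALINE,end_of_syringe,0
FOUR_DRUG_TOTAL,infusion_starts,3623
FOUR_DRUG_TOTAL,callback,3278
FOUR_DRUG_TOTAL,drive_engage_failure,57
FOUR_DRUG_TOTAL,end_of_infusion,56
FOUR_DRUG_TOTAL,near_end_of_infusion,454
FOUR_DRUG_TOTAL,occlusion_downstream,513
FOUR_DRUG_TOTAL,syringe_disengaged,78
FOUR_DRUG_TOTAL,end_of_syringe,5
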