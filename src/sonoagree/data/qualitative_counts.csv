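scope_kind,scope,region,cell,event,category,k,n,printed_pct
structure,c5_root,ISB,accuracy,,,13,15,86.7
structure,c5_root,ISB,fp,,,1,15,6.67
structure,c5_root,ISB,fn,,,1,15,6.7
structure,c6_root,ISB,accuracy,,,15,15,100
structure,c6_root,ISB,fp,,,0,15,0
structure,c6_root,ISB,fn,,,0,15,0
structure,axillary_artery,AxB,accuracy,,,15,15,100
structure,axillary_artery,AxB,fp,,,0,15,0
structure,axillary_artery,AxB,fn,,,0,15,0
structure,median_nerve,AxB,accuracy,,,13,15,86.7
structure,median_nerve,AxB,fp,,,2,15,13.3
structure,median_nerve,AxB,fn,,,0,15,0
structure,musculocutaneous_nerve,AxB,accuracy,,,12,15,80.0
structure,musculocutaneous_nerve,AxB,fp,,,0,15,0
structure,musculocutaneous_nerve,AxB,fn,,,3,15,20.0
structure,radial_nerve,AxB,accuracy,,,11,13,84.6
structure,radial_nerve,AxB,fp,,,2,13,15.4
structure,radial_nerve,AxB,fn,,,0,13,0
structure,ulnar_nerve,AxB,accuracy,,,14,15,93.3
structure,ulnar_nerve,AxB,fp,,,1,15,6.7
structure,ulnar_nerve,AxB,fn,,,0,15,0
structure,transverse_process,ESPB,accuracy,,,12,15,80.0
structure,transverse_process,ESPB,fp,,,0,15,0
structure,transverse_process,ESPB,fn,,,3,15,20.0
structure,pleura,ESPB,accuracy,,,14,15,93.3
structure,pleura,ESPB,fp,,,0,15,0
structure,pleura,ESPB,fn,,,1,15,6.7
structure,rectus_sheath,RSB,accuracy,,,15,15,100
structure,rectus_sheath,RSB,fp,,,0,15,0
structure,rectus_sheath,RSB,fn,,,0,15,0
structure,peritoneum,RSB,accuracy,,,15,15,100
structure,peritoneum,RSB,fp,,,0,15,0
structure,peritoneum,RSB,fn,,,0,15,0
structure,femoral_artery,ACB,accuracy,,,15,15,100
structure,femoral_artery,ACB,fp,,,0,15,0
structure,femoral_artery,ACB,fn,,,0,15,0
structure,saphenous_nerve,ACB,accuracy,,,14,15,93.3
structure,saphenous_nerve,ACB,fp,,,0,15,0
structure,saphenous_nerve,ACB,fn,,,1,15,6.7
structure,sciatic_nerve,SNB,accuracy,,,15,15,100
structure,sciatic_nerve,SNB,fp,,,0,15,0
structure,sciatic_nerve,SNB,fn,,,0,15,0
structure,c5_root,ISB,risk,nerve_trauma,increase,2,15,13.3
structure,c5_root,ISB,risk,nerve_trauma,no_change,0,15,0
structure,c5_root,ISB,risk,nerve_trauma,decrease,13,15,86.7
structure,c6_root,ISB,risk,nerve_trauma,increase,1,15,6.7
structure,c6_root,ISB,risk,nerve_trauma,no_change,3,15,20.0
structure,c6_root,ISB,risk,nerve_trauma,decrease,11,15,73.3
structure,axillary_artery,AxB,risk,last_arterial,increase,0,15,0
structure,axillary_artery,AxB,risk,last_arterial,no_change,0,15,0
structure,axillary_artery,AxB,risk,last_arterial,decrease,15,15,100
structure,median_nerve,AxB,risk,nerve_trauma,increase,1,15,6.7
structure,median_nerve,AxB,risk,nerve_trauma,no_change,3,15,20.0
structure,median_nerve,AxB,risk,nerve_trauma,decrease,11,15,73.3
structure,musculocutaneous_nerve,AxB,risk,nerve_trauma,increase,1,15,6.7
structure,musculocutaneous_nerve,AxB,risk,nerve_trauma,no_change,4,15,26.7
structure,musculocutaneous_nerve,AxB,risk,nerve_trauma,decrease,10,15,66.7
structure,radial_nerve,AxB,risk,nerve_trauma,increase,1,13,7.7
structure,radial_nerve,AxB,risk,nerve_trauma,no_change,1,13,7.7
structure,radial_nerve,AxB,risk,nerve_trauma,decrease,11,13,84.6
structure,ulnar_nerve,AxB,risk,nerve_trauma,increase,1,15,6.7
structure,ulnar_nerve,AxB,risk,nerve_trauma,no_change,1,15,6.7
structure,ulnar_nerve,AxB,risk,nerve_trauma,decrease,13,15,86.7
structure,es_muscle_group,ESPB,risk,pneumothorax_pleura,increase,1,15,6.7
structure,es_muscle_group,ESPB,risk,pneumothorax_pleura,no_change,3,15,20.0
structure,es_muscle_group,ESPB,risk,pneumothorax_pleura,decrease,11,15,73.33
structure,transverse_process,ESPB,risk,pneumothorax_pleura,increase,1,15,6.7
structure,transverse_process,ESPB,risk,pneumothorax_pleura,no_change,4,15,26.7
structure,transverse_process,ESPB,risk,pneumothorax_pleura,decrease,10,15,66.7
structure,pleura,ESPB,risk,pneumothorax_pleura,increase,2,15,13.3
structure,pleura,ESPB,risk,pneumothorax_pleura,no_change,2,15,13.3
structure,pleura,ESPB,risk,pneumothorax_pleura,decrease,11,15,73.3
structure,rectus_abdominis,RSB,risk,peritoneal_violation,increase,0,15,0
structure,rectus_abdominis,RSB,risk,peritoneal_violation,no_change,3,15,20.00
structure,rectus_abdominis,RSB,risk,peritoneal_violation,decrease,12,15,80.00
structure,rectus_sheath,RSB,risk,peritoneal_violation,increase,0,15,0
structure,rectus_sheath,RSB,risk,peritoneal_violation,no_change,2,15,13.3
structure,rectus_sheath,RSB,risk,peritoneal_violation,decrease,13,15,86.7
structure,peritoneum,RSB,risk,peritoneal_violation,increase,0,15,0
structure,peritoneum,RSB,risk,peritoneal_violation,no_change,3,15,20.0
structure,peritoneum,RSB,risk,peritoneal_violation,decrease,12,15,80.0
structure,femoral_artery,ACB,risk,last_arterial,increase,0,15,0
structure,femoral_artery,ACB,risk,last_arterial,no_change,0,15,0
structure,femoral_artery,ACB,risk,last_arterial,decrease,15,15,100
structure,saphenous_nerve,ACB,risk,nerve_trauma,increase,1,15,6.7
structure,saphenous_nerve,ACB,risk,nerve_trauma,no_change,2,15,13.3
structure,saphenous_nerve,ACB,risk,nerve_trauma,decrease,12,15,80.0
structure,sciatic_nerve,SNB,risk,nerve_trauma,increase,0,15,0
structure,sciatic_nerve,SNB,risk,nerve_trauma,no_change,2,15,13.3
structure,sciatic_nerve,SNB,risk,nerve_trauma,decrease,13,15,86.7
region,ISB,ISB,risk,last_arterial,increase,2,15,13.3
region,ISB,ISB,risk,last_arterial,no_change,2,15,13.3
region,ISB,ISB,risk,last_arterial,decrease,11,15,73.33
region,AxB,AxB,block_failure,,increase,2,15,13.33
region,AxB,AxB,block_failure,,no_change,3,15,20.00
region,AxB,AxB,block_failure,,decrease,10,15,66.67
region,ESPB,ESPB,block_failure,,increase,2,15,13.33
region,ESPB,ESPB,block_failure,,no_change,2,15,13.33
region,ESPB,ESPB,block_failure,,decrease,11,15,73.33
region,RSB,RSB,block_failure,,increase,0,15,0
region,RSB,RSB,block_failure,,no_change,1,15,6.67
region,RSB,RSB,block_failure,,decrease,14,15,93.33
region,ACB,ACB,block_failure,,increase,0,15,0
region,ACB,ACB,block_failure,,no_change,1,15,6.67
region,ACB,ACB,block_failure,,decrease,14,15,93.33
region,SNB,SNB,block_failure,,increase,1,15,6.67
region,SNB,SNB,block_failure,,no_change,1,15,6.67
region,SNB,SNB,block_failure,,decrease,13,15,86.67
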