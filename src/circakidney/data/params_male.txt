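# circakidney calibrated transport parameters (male rat)
# regenerated by circakidney.transport.calibrate(); do not edit by hand
PCT.f_active = 0.18566676266028262
PCT.f_passive = 0.3291724529470087
PCT.beta = 0.563682401869969
PCT.water_frac = 0.0
PCT.water_coupling = 0.0
PCT.clip_frac = 0.995
PST.f_active = 0.08000000000000002
PST.f_passive = 0.30564226200488664
PST.beta = 0.563682401869969
PST.water_frac = 0.0
PST.water_coupling = 0.0
PST.clip_frac = 0.995
ThinLimbs.f_active = 0.0
ThinLimbs.f_passive = 0.0
ThinLimbs.beta = 1.0
ThinLimbs.water_frac = 0.33944238541443644
ThinLimbs.water_coupling = 0.0
ThinLimbs.clip_frac = 0.995
mTAL.f_active = 0.30000000000000004
mTAL.f_passive = 0.0
mTAL.beta = 0.18505059650358732
mTAL.water_frac = 0.0
mTAL.water_coupling = 0.0
mTAL.clip_frac = 0.995
cTAL.f_active = 0.5143848911847482
cTAL.f_passive = 0.0
cTAL.beta = 0.18505059650358732
cTAL.water_frac = 0.0
cTAL.water_coupling = 0.0
cTAL.clip_frac = 0.995
DCT.f_active = 0.3889848471502225
DCT.f_passive = 0.0
DCT.beta = 0.05000000000000001
DCT.water_frac = 0.13285585292499785
DCT.water_coupling = 0.0
DCT.clip_frac = 0.995
CNT.f_active = 0.5881668425990308
CNT.f_passive = 0.0
CNT.beta = 0.05000000000000001
CNT.water_frac = 0.44342526129025744
CNT.water_coupling = 1.0
CNT.clip_frac = 0.995
CCD.f_active = 0.5881687331070767
CCD.f_passive = 0.0
CCD.beta = 0.05000000000000001
CCD.water_frac = 0.44342496152681393
CCD.water_coupling = 1.0
CCD.clip_frac = 0.995
OMCD.f_active = 0.05000000000000001
OMCD.f_passive = 0.0
OMCD.beta = 0.05000000000000001
OMCD.water_frac = 0.5611108769841202
OMCD.water_coupling = 1.0
OMCD.clip_frac = 0.995
IMCD.f_active = 0.05000000000000001
IMCD.f_passive = 0.0
IMCD.beta = 0.05000000000000001
IMCD.water_frac = 0.5611119378067231
IMCD.water_coupling = 1.0
IMCD.clip_frac = 0.995
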