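item,country,amount,currency,price_year,traded_good,source_tag
calibrated_drape,any,1.25,USD,2023,true,synthetic: drape manufacturer procurement price
uterotonic_dose,any,0.25,USD,2022,true,synthetic: supply-chain catalogue price
txa_dose,any,1.60,USD,2022,true,synthetic: wholesale price
iv_fluid_unit,any,0.80,USD,2022,true,synthetic: medical product price guide
hospital_day,kenya,1970,KES,2021,false,synthetic: service-delivery cost estimate
hospital_day,nigeria,16,USD,2022,false,synthetic: service-delivery cost estimate
hospital_day,south_africa,50,USD,2022,false,synthetic: service-delivery cost estimate
hospital_day,tanzania,13,USD,2022,false,synthetic: service-delivery cost estimate
icu_day,kenya,95,USD,2022,false,synthetic: secondary source; other countries via market basket
transfusion_unit,kenya,35,USD,2022,false,synthetic: blood bank estimate
transfusion_unit,nigeria,30,USD,2022,false,synthetic: blood bank estimate
transfusion_unit,south_africa,70,USD,2022,false,synthetic: blood bank estimate
transfusion_unit,tanzania,28,USD,2022,false,synthetic: blood bank estimate
transfer,kenya,25,USD,2022,false,synthetic: referral transport estimate; others via market basket
hysterectomy,kenya,220,USD,2022,false,synthetic: surgical package estimate
hysterectomy,nigeria,200,USD,2022,false,synthetic: surgical package estimate
hysterectomy,south_africa,520,USD,2022,false,synthetic: surgical package estimate
hysterectomy,tanzania,180,USD,2022,false,synthetic: surgical package estimate
nasg,any,20,USD,2022,true,synthetic: anti-shock garment unit price
balloon_tamponade,kenya,5,USD,2022,false,synthetic: improvised device materials and labor
balloon_tamponade,nigeria,5,USD,2022,false,synthetic: improvised device materials and labor
balloon_tamponade,tanzania,5,USD,2022,false,synthetic: improvised device materials and labor
balloon_tamponade,south_africa,60,USD,2022,true,synthetic: commercial device
personnel_min,kenya,0.20,USD,2022,false,synthetic: lowest-grade attending doctor salary per minute
personnel_min,nigeria,0.15,USD,2022,false,synthetic: lowest-grade attending doctor salary per minute
personnel_min,south_africa,0.55,USD,2022,false,synthetic: lowest-grade attending doctor salary per minute
personnel_min,tanzania,0.12,USD,2022,false,synthetic: lowest-grade attending doctor salary per minute
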