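drug,ka,k12,k21,k10
Abiraterone acetate,0.692,0.218,0.116,0.256
Acyclovir,0.604,0.559,0.031,0.012
Azithromycin,0.467,0.284,0.055,0.133
Benazepril,1.468,0.656,0.045,0.769
Bupropion,0.260,0.194,0.011,0.049
Candesartan cilexetil,0.400,0.116,0.105,0.252
Captopril,0.854,0.333,0.112,0.490
Celecoxib,0.342,0.175,0.010,0.166
Ciprofloxacin,0.448,0.044,0.019,0.392
Clopidogrel,1.216,0.163,0.061,0.982
Daclatasvir,0.864,0.506,0.246,0.168
Domperidone,1.726,0.847,0.451,0.502
Drotaverine,0.574,0.165,0.076,0.406
Glibenclamide,0.535,0.436,0.012,0.096
Hydrochlorothiazide,0.527,0.168,0.092,0.145
Isradipine,0.326,0.153,0.050,0.168
Itraconazole,0.340,0.183,0.063,0.120
Lacidipine,0.842,0.377,0.046,0.385
Lercanidipine hydrochloride,0.649,0.180,0.075,0.438
Levonorgestrel,0.691,0.434,0.178,0.107
Loratadine,0.989,0.402,0.063,0.548
Metformin,0.542,0.171,0.021,0.358
Mycophenolate mofetil,1.013,0.736,0.021,0.247
Naproxen,0.242,0.195,0.011,0.034
Olmesartan medoxomil,0.505,0.160,0.107,0.306
Oseltamivir phosphate,0.615,0.153,0.089,0.443
Quinapril,0.583,0.053,0.027,0.492
Repaglinide,1.396,0.314,0.203,1.003
Rilpivirine,0.210,0.130,0.051,0.036
Rosuvastatin,0.438,0.117,0.064,0.186
Silodosin,0.599,0.193,0.073,0.388
Simvastatin,1.023,0.201,0.161,0.178
Telmisartan,0.582,0.255,0.067,0.132
Tenofovir disoproxil fumarate,1.089,0.703,0.211,0.211
Terbinafine,0.703,0.252,0.133,0.373
Ticagrelor,0.570,0.208,0.063,0.331
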