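name,estimate,lo,hi,units,description
dep_a_n,0.14,0.10,0.18,kg ha-1 mm-0.5,N atmospheric deposition coefficient (times sqrt annual rain)
dep_a_p,0.023,0.015,0.031,kg ha-1 mm-0.5,P atmospheric deposition coefficient
dep_a_k,0.092,0.060,0.124,kg ha-1 mm-0.5,K atmospheric deposition coefficient
manure_n,0.012,0.008,0.016,fraction,N mass fraction of farmyard manure (dry)
manure_p,0.002,0.001,0.003,fraction,P mass fraction of farmyard manure
manure_k,0.015,0.010,0.020,fraction,K mass fraction of farmyard manure
manure_c,0.30,0.25,0.35,fraction,C mass fraction of farmyard manure
residue_n,0.006,0.004,0.008,fraction,N mass fraction of crop residue
residue_p,0.001,0.0007,0.0013,fraction,P mass fraction of crop residue
residue_k,0.012,0.008,0.016,fraction,K mass fraction of crop residue
residue_c,0.40,0.35,0.45,fraction,C mass fraction of crop residue
avail_n,0.5,0.4,0.6,fraction,first-year availability of organic N
avail_p,0.6,0.5,0.7,fraction,first-year availability of organic P
avail_k,0.9,0.8,1.0,fraction,first-year availability of organic K
humification,0.30,0.20,0.40,fraction,fraction of added organic C humified into SOC
k_soc,0.02,0.01,0.03,yr-1,first-order SOM carbon decay rate
ndfa,0.60,0.45,0.75,fraction,fraction of legume N derived from the atmosphere
legume_n_content,0.025,0.020,0.030,fraction,N mass fraction of legume biomass
rusle_r,4000,3000,5000,MJ mm ha-1 h-1 yr-1,rainfall erosivity factor
rusle_k,0.012,0.008,0.016,t ha h ha-1 MJ-1 mm-1,soil erodibility factor
ls_a,0.1,0.05,0.15,-,slope-length factor floor at zero slope
ls_b,0.03,0.02,0.04,-,slope-length factor slope coefficient
ls_exp,1.3,1.1,1.5,-,slope-length factor exponent on slope percent
cover_c,0.25,0.15,0.35,-,cover-management factor under maize-mixed cropping
practice_p,1.0,1.0,1.0,-,support-practice factor without conservation structures
swc_practice_p,0.5,0.3,0.7,-,support-practice factor with SWC structures
er_n,2.0,1.5,2.5,-,N enrichment ratio of eroded sediment
er_p,2.0,1.5,2.5,-,P enrichment ratio of eroded sediment
er_k,1.5,1.0,2.0,-,K enrichment ratio of eroded sediment
er_c,2.0,1.5,2.5,-,C enrichment ratio of eroded sediment
sdr,0.3,0.2,0.4,fraction,sediment delivery ratio to the downslope pixel
leach_rain,0.3,0.2,0.4,per 1000 mm,leaching-fraction rainfall coefficient
leach_clay,0.5,0.3,0.7,per 100 pct clay,leaching-fraction clay reduction coefficient
mineral_n_frac,0.02,0.01,0.03,fraction,share of total soil N in the leachable mineral pool
mineral_k_frac,0.05,0.03,0.07,fraction,share of total soil K in the exchangeable leachable pool
leach_k_factor,0.5,0.3,0.7,-,K leaching fraction relative to N
gas_base,0.05,0.03,0.07,fraction,baseline gaseous fraction of mineral N inputs
gas_rain,0.05,0.03,0.07,per 1000 mm,rainfall coefficient of the gaseous fraction
hi_maize,0.45,0.40,0.50,fraction,maize harvest index (grain over total above-ground biomass)
hi_legume,0.35,0.30,0.40,fraction,legume harvest index
maize_grain_n,0.016,0.013,0.019,fraction,N mass fraction of maize grain
maize_grain_p,0.0027,0.002,0.0034,fraction,P mass fraction of maize grain
maize_grain_k,0.0039,0.003,0.0048,fraction,K mass fraction of maize grain
legume_grain_n,0.035,0.030,0.040,fraction,N mass fraction of legume grain
legume_grain_p,0.0035,0.0025,0.0045,fraction,P mass fraction of legume grain
legume_grain_k,0.010,0.007,0.013,fraction,K mass fraction of legume grain
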