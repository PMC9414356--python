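system,phi_K_per_min,Tg_BDS_K,Tg_DSC_K,Tp_K,To_K,k1_per_s,k2_per_s,n
FL,5,,273,313.7,312.1,0.00527,,1.3
FL,10,271,274,317.3,316.2,0.01068,,1.7
FL,20,,276,322.8,321.1,0.04113,,2.2
FL,30,,278,325.2,322.9,0.06558,,2.6
FL+10wt%PVPcomm_Mn109,5,,274,318.9,313.9,0.00499,0.00212,2.3
FL+10wt%PVPcomm_Mn109,10,272,275,322.6,318.1,0.01206,0.00508,2.4
FL+10wt%PVPcomm_Mn109,20,,277,330.1,324.1,0.01916,0.00937,2.6
FL+10wt%PVPcomm_Mn109,30,,279,336.2,327.9,0.02433,0.01385,2.9
FL+10wt%PVP_Mn90,5,,277,337.2,330.2,0.00440,0.00283,2.8
FL+10wt%PVP_Mn90,10,277,279,341.9,334.1,0.00777,0.00535,2.9
FL+10wt%PVP_Mn90,20,,281,351.7,341.9,0.01601,0.01301,3.0
FL+10wt%PVP_Mn90,30,,283,359.4,348.1,0.02232,0.01841,2.9
FL+10wt%PVP_Mn190,5,,278,333.1,326.2,0.00415,0.00247,3.0
FL+10wt%PVP_Mn190,10,276,279,337.1,330.3,0.00683,0.00445,2.9
FL+10wt%PVP_Mn190,20,,282,347.3,338.1,0.01302,0.00957,2.6
FL+10wt%PVP_Mn190,30,,283,355.8,342.9,0.01814,0.01365,2.9
FL+10wt%PVP-OH_Mn190,5,,273,317.5,313.1,0.00517,0.00226,2.2
FL+10wt%PVP-OH_Mn190,10,274,275,321.7,317.2,0.01010,0.00453,2.4
FL+10wt%PVP-OH_Mn190,20,,277,329.3,323.1,0.01705,0.00895,2.8
FL+10wt%PVP-OH_Mn190,30,,279,336.2,327.2,0.02449,0.01671,2.7
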