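gas,quantity,t_c,salinity,expected
CH4,bunsen,-1,0,0.059201242
CH4,bunsen,5,0,0.049551884
CH4,bunsen,10,17.5,0.038600759
CH4,bunsen,15,35,0.030729272
CH4,bunsen,20,7,0.033153853
CH4,bunsen,25,35,0.025456934
CH4,bunsen,28,20,0.026539287
CO2,k0_mol_per_l_atm,0,0,0.077579739
CO2,k0_mol_per_l_atm,5,35,0.053582036
CO2,k0_mol_per_l_atm,10,17.5,0.049177980
CO2,k0_mol_per_l_atm,15,35,0.038438448
CO2,k0_mol_per_l_atm,20,7,0.037844075
CO2,k0_mol_per_l_atm,25,35,0.029058930
CO2,k0_mol_per_l_atm,30,20,0.027407638
CO2,k0_mol_per_l_atm,35,0,0.026462896
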