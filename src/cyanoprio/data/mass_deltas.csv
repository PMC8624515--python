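name,delta,direction,note
CH2 (methylation state),14.01565006,signed,methylation/demethylation; nominal 14.01 Da
O (oxidation state),15.99491462,signed,hydroxylation/oxidation
H2 (saturation state),2.01565006,signed,hydrogenation/dehydrogenation
H2O (condensation state),18.01056468,signed,hydration/dehydration
NH3,17.02654910,signed,amination/deamination
CO,27.99491462,signed,carbonylation loss/gain
CO2,43.98982924,signed,decarboxylation
Cl<->Br (halogen exchange),43.94948442,unsigned,chlorine/bromine substitution; nominal 43.94 Da
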