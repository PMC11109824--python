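# Default lipid component-group volumes (A^3 per lipid) and electron counts
# at 37 C, representative of the fluid-phase PE/PG-rich bacterial-mimic
# mixtures studied here. Values are literature-informed round numbers
# (component volumetry of fluid phospholipids); user-overridable per model.
component,volume,electrons
phos,180.0,97.0
cg,147.0,67.0
ch2,920.0,268.0
ch3,110.0,18.0
water,30.0,10.0
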