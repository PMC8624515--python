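# Positive-mode ESI adduct forms used for ion grouping and dereplication.
# m/z = (multimer * M + mass_offset) / charge
# Offsets are electron-corrected: H+ 1.00727647, Na+ 22.98922070, K+ 38.96315810.
adducts:
  - name: "[M+H]+"
    multimer: 1
    charge: 1
    mass_offset: 1.00727646688
  - name: "[M+Na]+"
    multimer: 1
    charge: 1
    mass_offset: 22.98922070099
  - name: "[M+K]+"
    multimer: 1
    charge: 1
    mass_offset: 38.96315810009
  - name: "[M+2H]2+"
    multimer: 1
    charge: 2
    mass_offset: 2.01455293376
  - name: "[2M+H]+"
    multimer: 2
    charge: 1
    mass_offset: 1.00727646688
  - name: "[2M+Na]+"
    multimer: 2
    charge: 1
    mass_offset: 22.98922070099
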