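"""Regional electrode sets shared by synthesis and staging."""

OCCIPITAL_SET = ("O1", "O2", "P3", "Pz", "P4", "T5", "T6")
FRONTAL_SET = ("Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8")
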