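{
 "ebox_mode": "basal",
 "h16_returns_monomers": true,
 "h16_compartment": "cytoplasmic",
 "genes": {
  "hes1": {
   "k0": "k_0,HES1",
   "repressors": [
    {"regulator": "hes1_prot_nuc", "H": "H_HES1", "h": 3, "n": 2},
    {"regulator": "rbpj_prot_nuc", "H": "K_HES1", "h": 2, "n": 1}
   ],
   "rbp_site_count": 2
  },
  "rbpj": {
   "k0": "k_0,RBP-J",
   "repressors": [
    {"regulator": "hes1_prot_nuc", "H": "H_HES1", "h": 3, "n": 2},
    {"regulator": "rbpj_prot_nuc", "H": "H_RBP-J", "h": 3, "n": 1}
   ],
   "rbp_site_count": 3
  },
  "notch1": {
   "k0": "k_0,NOTCH1",
   "repressors": [
    {"regulator": "hes1_prot_nuc", "H": "H_HES1", "h": 1, "n": 2},
    {"regulator": "rbpj_prot_nuc", "H": "H_RBP-J", "h": 2, "n": 1}
   ],
   "rbp_site_count": 2
  },
  "mash1": {
   "k0": "k_0,MASH1",
   "repressors": [
    {"regulator": "hes1_prot_nuc", "H": "H_HES1", "h": 1, "n": 2}
   ],
   "rbp_site_count": 0,
   "ebox": {"H": "H_MASH1", "g": 1, "mode": "basal"},
   "dominant_negative": true
  },
  "hes6": {
   "k0": "k_0,HES6",
   "repressors": [],
   "rbp_site_count": 0,
   "ebox": {"H": "H_HES6", "g": 1, "mode": "gated"}
  }
 }
}
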