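{
 "k_d,HRN": 0.028,
 "k_d,RRN": 0.028,
 "k_d,NRN": 0.028,
 "k_d,MRN": 0.028,
 "k_d,H6RN": 0.028,
 "k_d,HES1": 0.031,
 "k_d,RBP": 0.031,
 "k_d,NOTCH": 0.031,
 "k_d,MASH1": 0.031,
 "k_d,HES6": 0.031,
 "k_d,[M-E47]": 0.031,
 "k_d,HES1,6": 0.031,
 "k_d,NRB": 0.003,
 "k_dom,neg": 15.0,
 "k_0,HES1": 1.0,
 "k_0,RBP-J": 1.0,
 "k_0,NOTCH1": 1.0,
 "k_0,MASH1": 1.0,
 "k_0,[M-E47]": 0.1,
 "k_0,HES6": 1.0,
 "k_0,HES1,6": 0.001,
 "c_HES1": 0.2,
 "c_RBP-J": 0.2,
 "c_NOTCH1": 0.2,
 "c_MASH1": 0.2,
 "c_HES6": 0.2,
 "H_HES1": 10.0,
 "H_RBP-J": 10.0,
 "K_HES1": 10.0,
 "H_MASH1": 10.0,
 "H_HES6": 10.0,
 "a_mRNA": 0.05,
 "b_prot": 0.05,
 "k_d,NICD": 0.0385,
 "k_0,Nicd-RBP": 0.1,
 "K_NICD": 1.0,
 "K_RBP-J": 1.0,
 "k_NICD": 0.1,
 "E47_total": 1.0,
 "k_NICD,import": 0.1
}
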