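{
 "k_d,HRN": 0.0363,
 "k_d,RRN": 0.0242,
 "k_d,NRN": 0.0390,
 "k_d,MRN": 0.0485,
 "k_d,H6RN": 0.0520,
 "k_d,HES1": 0.0379,
 "k_d,RBP": 0.0233,
 "k_d,NOTCH": 0.0311,
 "k_d,MASH1": 0.0070,
 "k_d,HES6": 0.0079,
 "k_d,[M-E47]": 0.0581,
 "k_d,HES1,6": 0.0289,
 "k_d,NRB": 0.0028,
 "k_dom,neg": 18.6882,
 "k_0,HES1": 1.0056,
 "k_0,RBP-J": 0.3867,
 "k_0,NOTCH1": 1.5926,
 "k_0,MASH1": 0.3876,
 "k_0,[M-E47]": 0.0630,
 "k_0,HES6": 1.0749,
 "k_0,HES1,6": 0.0002,
 "c_HES1": 0.3635,
 "c_RBP-J": 0.0969,
 "c_NOTCH1": 0.0820,
 "c_MASH1": 0.1049,
 "c_HES6": 0.3594,
 "H_HES1": 3.7486,
 "H_RBP-J": 1.9378,
 "K_HES1": 7.9462,
 "H_MASH1": 5.1724,
 "H_HES6": 17.4502,
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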