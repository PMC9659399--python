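emotion,c01,c02,c03,c04,c05,c06,c07,c08,c09,c10,c11,c12,c13,c14,c15,c16,c17,c18,c19,c20,c21,c22,c23,c24,c25,c26,c27,c28,c29,c30,c31,c32,c33,c34,c35,c36,c37,c38,c39,c40,c41,c42,c43,c44,c45,c46
happy,0.4,0.03,0.03,0.03,0.6,0.5,0.03,0.03,0.03,0.8,0.7,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.45,0.45,0.375,0.375,0.6,0.6,0.03,0.03,0.03,0.03,0.03,0.03
fear,0.7,0.6,0.4,0.8,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.5,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.45,0.45,0.3,0.3,0.6,0.6,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.375,0.375,0.03,0.03
angry,0.03,0.03,0.8,0.03,0.03,0.03,0.5,0.7,0.6,0.03,0.03,0.03,0.03,0.4,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.6,0.6,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03
sad,0.03,0.03,0.03,0.03,0.03,0.4,0.03,0.03,0.7,0.03,0.03,0.03,0.8,0.03,0.6,0.03,0.5,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.3,0.3,0.03,0.03,0.6,0.6,0.375,0.375,0.03,0.03
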