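behavior	parade	demonstration	attack	fight	chase	impact	feint	temporary retreat	retreat
parade		100
demonstration	30.08		69.92
attack				33.09	33.84	18.04	15.03
fight					32.82				67.18
chase						50.60			49.40
impact					23.99				76.01
feint						40.12		24.20	35.68
temporary retreat		45.47					54.53
retreat	52.21	47.79
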