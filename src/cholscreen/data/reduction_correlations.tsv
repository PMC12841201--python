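gene	brainstem_100	brainstem_250	forebrain_100	forebrain_250
Aldh7a1	0.085	0.268	0.636	0.571
Cept1	0.996	0.963	0.771	0.821
Slc44a1	0.913	0.998	0.521	0.962
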