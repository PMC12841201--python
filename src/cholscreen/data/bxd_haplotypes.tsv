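gene	B6	BXD51	BXD73	BXD2
Aldh7a1	B6	B6	B6	D2
Aldh9a1	B6	B6	B6	B6
Bhmt	B6	B6	B6	D2
Bhmt2	B6	B6	B6	D2
Chat	NV	NV	NV	NV
Chdh	NV	NV	NV	NV
Chka	B6	B6	R	B6
Chkb	H	H	B6	B6
Cept1	B6	D2	D2	D2
Chpt1	B6	D2	B6	D2
Pcyt1a	B6	B6	B6	B6
Pcyt1b	NV	NV	NV	NV
Mtr	NV	NV	NV	NV
Pemt	NV	NV	NV	NV
Slc22a1	NV	NV	NV	NV
Slc22a3	B6	D2	D2	B6
Slc5a7	B6	B6	D2	D2
Slc44a1	B6	D2	D2	B6
Slc44a2	B6	B6	B6	B6
Slc44a3	B6	D2	B6	D2
Slc44a4	NV	NV	NV	NV
Slc44a5	B6	R	R	R
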