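gene	B6	BXD51	BXD73	BXD2
Aldh7a1	17.8	17.4	17.6	n/a
Bhmt	22	22	22	n/a
Bhmt2	17	17	17	n/a
Cept1	16.4	16.4	16.2	n/a
Slc44a1	12.7	12.6	12.9	n/a
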