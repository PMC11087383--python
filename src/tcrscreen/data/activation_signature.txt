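IFNG
IL2
TNF
IL2RA
CD69
TNFRSF9
GZMB
GZMA
GZMK
PRF1
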