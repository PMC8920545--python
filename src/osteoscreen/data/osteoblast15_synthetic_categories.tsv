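set_name	category
SYN_OSTEOBLAST_TRANSCRIPTION_FACTORS	transcription_factor
SYN_OSTEOBLAST_DIFFERENTIATION_CORE	differentiation
SYN_OSTEOBLAST_DIFFERENTIATION_BMP	differentiation
SYN_OSTEOBLAST_DIFFERENTIATION_WNT	differentiation
SYN_OSTEOBLAST_DIFFERENTIATION_TGFB	differentiation
SYN_OSTEOBLAST_DIFFERENTIATION_IGF	differentiation
SYN_OSTEOBLAST_DIFFERENTIATION_FGF	differentiation
SYN_OSTEOBLAST_DIFFERENTIATION_ECM	differentiation
SYN_OSTEOBLAST_DIFFERENTIATION_MINERALIZATION	differentiation
SYN_OSTEOBLAST_DIFFERENTIATION_HEDGEHOG	differentiation
SYN_OSTEOBLAST_DEVELOPMENT	development
SYN_OSTEOBLAST_PROLIFERATION_CELL_CYCLE	proliferation
SYN_OSTEOBLAST_PROLIFERATION_GROWTH	proliferation
SYN_OSTEOBLAST_PROLIFERATION_SIGNALS	proliferation
SYN_OSTEOBLAST_SIGNALING_PTH	signaling
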