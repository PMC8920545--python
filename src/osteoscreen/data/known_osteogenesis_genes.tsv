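gene	note
RUNX2	master osteoblast transcription factor
SP7	osterix, osteoblast commitment
BGLAP	osteocalcin, mature osteoblast marker
SPP1	osteopontin, matrix protein
ALPL	alkaline phosphatase, mineralization
COL1A1	type I collagen, bone matrix
BMP2	canonical osteoinductive ligand
CTNNB1	Wnt/beta-catenin effector
FOXO1	acts upstream of RUNX2 induction
IL6	inflammatory regulator of osteogenesis
CXCL12	stromal-derived factor, BMSC niche
JUN	AP-1 component in osteoblast signaling
NGF	neurotrophin with reported bone roles
FRZB	secreted Wnt modulator in skeletal tissue
COMP	cartilage oligomeric matrix protein
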