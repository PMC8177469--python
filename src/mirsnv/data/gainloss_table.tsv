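# Reference gain/loss table: published per-gene summary of miRNA binding
# sites gained and lost through recurrent 3'-UTR SNVs (>=10 of 35 patients)
# in an MTLE RNA-seq cohort, transcribed as printed. Empty or "Nil" cells
# denote an empty miRNA set. The n_gained/n_lost columns transcribe the
# count printed in each cell; the gained/lost columns transcribe the
# parenthetical miRNA id lists as printed (the ATP1A2 lost cell prints 14
# but enumerates 13 ids). Columns: gene, relatedness, n_gained, gained,
# n_lost, lost
# (miRNA id lists semicolon-separated).
gene	relatedness	n_gained	gained	n_lost	lost
FGF12	EG	1	hsa-miR-4760-3p	0	Nil
ATP1A2	ERG	11	hsa-miR-4271;hsa-miR-4725-3p;hsa-miR-4747-5p;hsa-miR-6780b-5p;hsa-miR-6783-5p;hsa-miR-3161;hsa-miR-371a-3p;hsa-miR-152-5p;hsa-miR-204-3p;hsa-miR-4314;hsa-miR-4646-5p	14	hsa-miR-1224-3p;hsa-miR-1260a;hsa-miR-1260b;hsa-miR-3153;hsa-miR-4270;hsa-miR-4502;hsa-miR-4713-5p;hsa-miR-532-3p;hsa-miR-5584-5p;hsa-miR-6733-3p;hsa-miR-6733-5p;hsa-miR-6739-5p;hsa-miR-6750-5p
SLC1A3	ERG	2	hsa-miR-3668;hsa-miR-576-3p	0	Nil
TUBB4A	ERG	1	hsa-miR-4742-5p	5	hsa-miR-4270;hsa-miR-4763-3p;hsa-miR-6722-3p;hsa-miR-6754-5p;hsa-miR-9500
RFX3	Potential EAG	4	hsa-miR-552-5p;hsa-miR-4674;hsa-miR-760;hsa-miR-7158-5p	8	hsa-miR-1291;hsa-miR-146b-3p;hsa-miR-339-5p;hsa-miR-4421;hsa-miR-5699-3p;hsa-miR-6724-5p;hsa-miR-6773-5p;hsa-miR-6775-3p
FAR1	ERG	4	hsa-miR-497-3p;hsa-miR-548aa;hsa-miR-548ap-3p;hsa-miR-548t-3p	0	Nil
GRIN2B	EG	3	hsa-miR-124-5p;hsa-miR-498-5p;hsa-miR-513b-3p	1	hsa-miR-3974
NAPB	Potential EAG	3	hsa-miR-6818-5p;hsa-miR-6867-5p;hsa-miR-3177-5p	0	Nil
CNTNAP2	Neurodevelopment associated EG	1	hsa-miR-4766-5p	2	hsa-miR-1299;hsa-miR-875-3p
HECW2	Potential EAG	1	hsa-miR-136-5p	0	Nil
NRG3	Potential EAG	1	hsa-miR-580-3p	0	Nil
ACADSB	Not found	4	hsa-miR-4499;hsa-miR-548u;hsa-miR-7161-5p;hsa-miR-4724-3p	2	hsa-miR-1257;hsa-miR-5586-3p
GALC	ERG	1	hsa-miR-556-3p	5	hsa-miR-3158-5p;hsa-miR-4418;hsa-miR-509-3-5p;hsa-miR-509-5p;hsa-miR-574-3p
SLC12A6	Neurodevelopment associated EG	4	hsa-miR-143-3p;hsa-miR-4756-3p;hsa-miR-4770;hsa-miR-6088	0	
ATP8A2	Potential EAG	2	hsa-miR-186-3p;hsa-miR-4422	2	hsa-miR-570-3p;hsa-miR-645
HERC2	ERG	6	hsa-miR-30c-1-3p;hsa-miR-30c-2-3p;hsa-miR-5192;hsa-miR-6731-5p;hsa-miR-6788-5p;hsa-miR-8085	9	hsa-miR-1273h-5p;hsa-miR-149-3p;hsa-miR-30b-3p;hsa-miR-6779-5p;hsa-miR-6785-5p;hsa-miR-6795-5p;hsa-miR-6805-5p;hsa-miR-6883-5p;hsa-miR-6887-5p
MAPRE2	ERG	1	hsa-miR-4255	3	hsa-miR-4738-3p;hsa-miR-548g-3p;hsa-miR-892c-3p
PGAP1	ERG	1	hsa-miR-510-3p	4	hsa-miR-1250-3p;hsa-miR-3617-5p;hsa-miR-4635;hsa-miR-641
MMADHC	ERG	0	Nil	1	hsa-miR-1277-5p
FBXO28	Potential EAG	0	Nil	4	hsa-miR-135a-3p;hsa-miR-3162-5p;hsa-miR-3163;hsa-miR-5700
GRIN2A	EG	0	Nil	3	hsa-miR-208a-5p;hsa-miR-208b-5p;hsa-miR-627-3p
CACNB4	EG	0		1	hsa-miR-3165
TDP2	ERG	0	Nil	1	hsa-miR-607
ABHD12	ERG	0	Nil	1	hsa-miR-4485-5p
RBPJ	Potential EAG	0	Nil	1	hsa-miR-4666a-5p
PCMT1	Not found	0	Nil	1	hsa-miR-584-5p
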