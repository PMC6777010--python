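# SYNTHETIC stand-in gene coordinate table (tsv5 dialect, hg38-style).
# This is NOT an extract of any released annotation file: it is a
# hand-built reconstruction covering only the loci exercised by the
# bundled worked examples, with approximate hg38 coordinates (0-based
# half-open) and cytobands.  Gene ORDER along each chromosome matches the
# reference assembly; base-pair positions are approximate.  For real
# analyses supply a complete coordinate table via --coordinates.
# columns: symbol <TAB> chrom <TAB> start <TAB> end <TAB> cytoband
NOTCH2	chr1	119911553	120069703	1p12
ADAM30	chr1	120087864	120090838	1p12
PDE4DIP	chr1	144852388	145076186	1q21.2
BCL9	chr1	147013182	147098016	1q21.2
MCL1	chr1	150574551	150579738	1q21.2
ARNT	chr1	150809713	150876710	1q21.3
MLLT11	chr1	151032453	151040970	1q21.3
TPM3	chr1	154155295	154192100	1q21.3
MUC1	chr1	155185824	155192916	1q22
LMNA	chr1	156082573	156140081	1q22
PRCC	chr1	156736274	156769875	1q23.1
NTRK1	chr1	156815640	156881850	1q23.1
FGFR3	chr4	1793293	1808872	4p16.3
KCNIP4	chr4	20730558	21950353	4p15.31
SLC34A2	chr4	25655477	25680370	4p15.2
RHOH	chr4	40192601	40246173	4p14
PHOX2B	chr4	41744082	41748725	4p13
FIP1L1	chr4	53377628	53457698	4q12
CHIC2	chr4	53787116	53812816	4q12
PDGFRA	chr4	54229097	54298247	4q12
KIT	chr4	54657928	54740715	4q12
KDR	chr4	55078481	55125595	4q12
IL7R	chr5	35856891	35879603	5p13.2
SKP2	chr5	36152090	36184722	5p13.2
LIFR	chr5	38474963	38608456	5p13.1
RICTOR	chr5	38938022	39074510	5p13.1
NNT	chr5	43602634	43707535	5p12
FGF10	chr5	44300685	44389706	5p12
IL6ST	chr5	55935095	55994992	5q11.2
MAP3K1	chr5	56815574	56896156	5q11.2
GRM3	chr7	86673081	86894309	7q21.11
ABCB4	chr7	87365605	87480435	7q21.12
AKAP9	chr7	91940862	92110673	7q21.2
CDK6	chr7	92604921	92836561	7q21.2
TRRAP	chr7	98878532	99012329	7q22.1
CUX1	chr7	101819141	102157236	7q22.1
NAMPT	chr7	106248305	106286326	7q22.3
PIK3CG	chr7	106865278	106908978	7q22.3
PRKAR2B	chr7	107002070	107119917	7q22.3
MET	chr7	116672196	116798377	7q31.2
POT1	chr7	124822386	124929983	7q31.33
SND1	chr7	127652213	128092455	7q32.1
SMO	chr7	129188633	129213545	7q32.1
MEN1	chr11	64803514	64811294	11q13.1
CAPN1	chr11	65175481	65206745	11q13.1
CCND1	chr11	69641156	69654474	11q13.3
FGF19	chr11	69699448	69705665	11q13.3
FGF4	chr11	69771016	69773373	11q13.3
FGF3	chr11	69810000	69819066	11q13.3
NUMA1	chr11	72002864	72080195	11q13.4
PAK1	chr11	77322017	77474635	11q13.5
GAB2	chr11	78215287	78417846	11q14.1
CDK4	chr12	57747727	57756013	12q14.1
LRIG3	chr12	58864123	58916738	12q14.1
WIF1	chr12	64968577	65039194	12q14.3
HMGA2	chr12	65824460	65966291	12q14.3
MDM2	chr12	68808172	68850686	12q15
FRS2	chr12	69456897	69579973	12q15
SPRED1	chr15	38252086	38357249	15q14
IVD	chr15	40405485	40421396	15q15.1
B2M	chr15	44711477	44718877	15q21.1
USP8	chr15	50424822	50501200	15q21.2
MYO5A	chr15	52307282	52529050	15q21.2
C15ORF65	chr15	56205010	56209742	15q21.3
TCF12	chr15	57210832	57580714	15q21.3
MAP2K1	chr15	66386837	66492312	15q22.31
SMAD3	chr15	67063763	67195195	15q22.33
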