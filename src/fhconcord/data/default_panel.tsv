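symbol	inheritance	haploinsufficient	acmg_sf	cancer_types	transcript
AIP	AD	yes	false	pituitary	NM_100001.2
ALK	AD	no	false	neuroblastoma	NM_100098.2
APC	AD	yes	true	colorectal	NM_100195.2
ATM	AD	yes	false	breast;pancreatic	NM_100292.2
AXIN2	AD	yes	false	colorectal	NM_100389.2
BAP1	AD	yes	false	melanoma;mesothelioma;kidney	NM_100486.2
BARD1	AD	yes	false	breast	NM_100583.2
BLM	AR	no	false	leukemia;colorectal	NM_100680.2
BMPR1A	AD	yes	true	colorectal	NM_100777.2
BRCA1	AD	yes	true	breast;ovarian;pancreatic	NM_100874.2
BRCA2	AD	yes	true	breast;ovarian;pancreatic;prostate	NM_100971.2
BRIP1	AD	yes	false	breast;ovarian	NM_101068.2
BUB1B	AR	no	false	wilms;sarcoma	NM_101165.2
CDC73	AD	yes	false	parathyroid	NM_101262.2
CDH1	AD	yes	false	gastric;breast	NM_101359.2
CDK4	AD	no	false	melanoma	NM_101456.2
CDKN1C	AD	unknown	false	wilms	NM_101553.2
CDKN2A	AD	yes	false	melanoma;pancreatic	NM_101650.2
CEBPA	AD	unknown	false	leukemia	NM_101747.2
CHEK2	AD	yes	false	breast;colorectal;prostate	NM_101844.2
CYLD	AD	yes	false	skin_nonmelanoma	NM_101941.2
DDB2	AR	no	false	skin_nonmelanoma	NM_102038.2
DICER1	AD	yes	false	thyroid;ovarian;pleuropulmonary_blastoma	NM_102135.2
EGFR	AD	no	false	lung	NM_102232.2
EPCAM	AD	unknown	false	colorectal;endometrial	NM_102329.2
ERCC2	AR	no	false	skin_nonmelanoma	NM_102426.2
ERCC3	AR	no	false	skin_nonmelanoma	NM_102523.2
ERCC4	AR	no	false	skin_nonmelanoma	NM_102620.2
ERCC5	AR	no	false	skin_nonmelanoma	NM_102717.2
EXT1	AD	yes	false	bone	NM_102814.2
EXT2	AD	yes	false	bone	NM_102911.2
FANCA	AR	no	false	leukemia	NM_103008.2
FANCB	XL	no	false	leukemia	NM_103105.2
FANCC	AR	no	false	leukemia	NM_103202.2
FANCD2	AR	no	false	leukemia	NM_103299.2
FANCG	AR	no	false	leukemia	NM_103396.2
FH	AD	yes	false	kidney;leiomyomatosis	NM_103493.2
FLCN	AD	yes	false	kidney	NM_103590.2
GATA2	AD	yes	false	leukemia	NM_103687.2
GPC3	XL	yes	false	wilms;liver	NM_103784.2
HNF1A	AD	unknown	false	liver	NM_103881.2
HRAS	AD	no	false	urothelial	NM_103978.2
KIT	AD	no	false	gastrointestinal_stromal	NM_104075.2
LZTR1	AD	yes	false	schwannoma	NM_104172.2
MAX	AD	yes	false	pheochromocytoma	NM_104269.2
MEN1	AD	yes	true	pancreatic;parathyroid	NM_104366.2
MET	AD	no	false	kidney	NM_104463.2
MITF	AD	no	false	melanoma;kidney	NM_104560.2
MLH1	AD	yes	true	colorectal;endometrial;ovarian	NM_104657.2
MSH2	AD	yes	true	colorectal;endometrial;ovarian	NM_104754.2
MSH6	AD	yes	true	colorectal;endometrial;ovarian	NM_104851.2
MUTYH	AR	no	true	colorectal	NM_104948.2
NBN	AR	no	false	breast;leukemia	NM_105045.2
NF1	AD	yes	false	sarcoma;brain;breast	NM_105142.2
NF2	AD	yes	true	brain	NM_105239.2
NSD1	AD	yes	false	wilms	NM_105336.2
PALB2	AD	yes	false	breast;pancreatic	NM_105433.2
PHOX2B	AD	unknown	false	neuroblastoma	NM_105530.2
PMS2	AD	yes	true	colorectal;endometrial	NM_105627.2
POLD1	AD	no	false	colorectal;endometrial	NM_105724.2
POLE	AD	no	false	colorectal	NM_105821.2
POT1	AD	unknown	false	melanoma;glioma	NM_105918.2
PRF1	AR	no	false	lymphoma	NM_106015.2
PRKAR1A	AD	yes	false	thyroid;adrenocortical	NM_106112.2
PTCH1	AD	yes	false	skin_nonmelanoma;brain	NM_106209.2
PTEN	AD	yes	true	breast;thyroid;endometrial	NM_106306.2
RAD50	AD	yes	false	breast	NM_106403.2
RAD51C	AD	yes	false	breast;ovarian	NM_106500.2
RAD51D	AD	yes	false	breast;ovarian	NM_106597.2
RB1	AD	yes	true	retinoblastoma;sarcoma	NM_106694.2
RECQL4	AR	no	false	bone;skin_nonmelanoma	NM_106791.2
RET	AD	no	true	thyroid;pheochromocytoma	NM_106888.2
RUNX1	AD	yes	false	leukemia	NM_106985.2
SBDS	AR	no	false	leukemia	NM_107082.2
SDHA	AD	unknown	false	paraganglioma;gastrointestinal_stromal	NM_107179.2
SDHAF2	AD	yes	true	paraganglioma	NM_107276.2
SDHB	AD	yes	true	paraganglioma;kidney	NM_107373.2
SDHC	AD	yes	true	paraganglioma	NM_107470.2
SDHD	AD	yes	true	paraganglioma	NM_107567.2
SLX4	AR	no	false	leukemia	NM_107664.2
SMAD4	AD	yes	true	colorectal;gastric	NM_107761.2
SMARCA4	AD	yes	false	ovarian;rhabdoid	NM_107858.2
SMARCB1	AD	yes	false	rhabdoid;schwannoma	NM_107955.2
STK11	AD	yes	true	colorectal;breast;pancreatic	NM_108052.2
SUFU	AD	yes	false	brain;skin_nonmelanoma	NM_108149.2
TERT	AD	no	false	melanoma;leukemia	NM_108246.2
TMEM127	AD	yes	false	pheochromocytoma	NM_108343.2
TP53	AD	yes	true	breast;sarcoma;brain;adrenocortical	NM_108440.2
TSC1	AD	yes	true	kidney;brain	NM_108537.2
TSC2	AD	yes	true	kidney;brain	NM_108634.2
VHL	AD	yes	true	kidney;pheochromocytoma	NM_108731.2
WRN	AR	no	false	sarcoma;thyroid;melanoma	NM_108828.2
WT1	AD	yes	true	wilms	NM_108925.2
XPC	AR	no	false	skin_nonmelanoma	NM_109022.2
XRCC2	AR	no	false	breast	NM_109119.2
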