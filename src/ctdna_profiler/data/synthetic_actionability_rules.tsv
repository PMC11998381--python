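gene	alteration_class	origin	framework	level	therapy
BRCA1	LOF_SNV	any	ONCOKB	1	PARP inhibitor
BRCA1	LOF_SNV	any	ESCAT	I	PARP inhibitor
BRCA1	HOMDEL	any	ONCOKB	1	PARP inhibitor
BRCA1	HOMDEL	any	ESCAT	I	PARP inhibitor
BRCA2	LOF_SNV	any	ONCOKB	1	PARP inhibitor
BRCA2	LOF_SNV	any	ESCAT	I	PARP inhibitor
BRCA2	HOMDEL	any	ONCOKB	1	PARP inhibitor
BRCA2	HOMDEL	any	ESCAT	I	PARP inhibitor
ATM	LOF_SNV	any	ONCOKB	1	PARP inhibitor
ATM	LOF_SNV	any	ESCAT	II	PARP inhibitor
ATM	HOMDEL	any	ONCOKB	1	PARP inhibitor
ATM	HOMDEL	any	ESCAT	II	PARP inhibitor
BRIP1	LOF_SNV	any	ONCOKB	1	PARP inhibitor
BRIP1	LOF_SNV	any	ESCAT	II	PARP inhibitor
BRIP1	HOMDEL	any	ONCOKB	1	PARP inhibitor
BRIP1	HOMDEL	any	ESCAT	II	PARP inhibitor
BARD1	LOF_SNV	any	ONCOKB	1	PARP inhibitor
BARD1	LOF_SNV	any	ESCAT	II	PARP inhibitor
BARD1	HOMDEL	any	ONCOKB	1	PARP inhibitor
BARD1	HOMDEL	any	ESCAT	II	PARP inhibitor
CDK12	LOF_SNV	any	ONCOKB	1	PARP inhibitor
CDK12	LOF_SNV	any	ESCAT	II	PARP inhibitor
CDK12	HOMDEL	any	ONCOKB	1	PARP inhibitor
CDK12	HOMDEL	any	ESCAT	II	PARP inhibitor
CHEK1	LOF_SNV	any	ONCOKB	1	PARP inhibitor
CHEK1	LOF_SNV	any	ESCAT	II	PARP inhibitor
CHEK1	HOMDEL	any	ONCOKB	1	PARP inhibitor
CHEK1	HOMDEL	any	ESCAT	II	PARP inhibitor
CHEK2	LOF_SNV	any	ONCOKB	1	PARP inhibitor
CHEK2	LOF_SNV	any	ESCAT	II	PARP inhibitor
CHEK2	HOMDEL	any	ONCOKB	1	PARP inhibitor
CHEK2	HOMDEL	any	ESCAT	II	PARP inhibitor
FANCL	LOF_SNV	any	ONCOKB	1	PARP inhibitor
FANCL	LOF_SNV	any	ESCAT	II	PARP inhibitor
FANCL	HOMDEL	any	ONCOKB	1	PARP inhibitor
FANCL	HOMDEL	any	ESCAT	II	PARP inhibitor
PALB2	LOF_SNV	any	ONCOKB	1	PARP inhibitor
PALB2	LOF_SNV	any	ESCAT	II	PARP inhibitor
PALB2	HOMDEL	any	ONCOKB	1	PARP inhibitor
PALB2	HOMDEL	any	ESCAT	II	PARP inhibitor
PPP2R2A	LOF_SNV	any	ONCOKB	1	PARP inhibitor
PPP2R2A	LOF_SNV	any	ESCAT	II	PARP inhibitor
PPP2R2A	HOMDEL	any	ONCOKB	1	PARP inhibitor
PPP2R2A	HOMDEL	any	ESCAT	II	PARP inhibitor
RAD51B	LOF_SNV	any	ONCOKB	1	PARP inhibitor
RAD51B	LOF_SNV	any	ESCAT	II	PARP inhibitor
RAD51B	HOMDEL	any	ONCOKB	1	PARP inhibitor
RAD51B	HOMDEL	any	ESCAT	II	PARP inhibitor
RAD51C	LOF_SNV	any	ONCOKB	1	PARP inhibitor
RAD51C	LOF_SNV	any	ESCAT	II	PARP inhibitor
RAD51C	HOMDEL	any	ONCOKB	1	PARP inhibitor
RAD51C	HOMDEL	any	ESCAT	II	PARP inhibitor
RAD51D	LOF_SNV	any	ONCOKB	1	PARP inhibitor
RAD51D	LOF_SNV	any	ESCAT	II	PARP inhibitor
RAD51D	HOMDEL	any	ONCOKB	1	PARP inhibitor
RAD51D	HOMDEL	any	ESCAT	II	PARP inhibitor
RAD54L	LOF_SNV	any	ONCOKB	1	PARP inhibitor
RAD54L	LOF_SNV	any	ESCAT	II	PARP inhibitor
RAD54L	HOMDEL	any	ONCOKB	1	PARP inhibitor
RAD54L	HOMDEL	any	ESCAT	II	PARP inhibitor
NBN	LOF_SNV	any	ONCOKB	1	PARP inhibitor
NBN	LOF_SNV	any	ESCAT	II	PARP inhibitor
NBN	HOMDEL	any	ONCOKB	1	PARP inhibitor
NBN	HOMDEL	any	ESCAT	II	PARP inhibitor
RAD50	LOF_SNV	any	ONCOKB	1	PARP inhibitor
RAD50	LOF_SNV	any	ESCAT	II	PARP inhibitor
RAD50	HOMDEL	any	ONCOKB	1	PARP inhibitor
RAD50	HOMDEL	any	ESCAT	II	PARP inhibitor
FANCA	LOF_SNV	any	ONCOKB	1	PARP inhibitor
FANCA	LOF_SNV	any	ESCAT	II	PARP inhibitor
FANCA	HOMDEL	any	ONCOKB	1	PARP inhibitor
FANCA	HOMDEL	any	ESCAT	II	PARP inhibitor
ATR	LOF_SNV	any	ONCOKB	1	PARP inhibitor
ATR	LOF_SNV	any	ESCAT	II	PARP inhibitor
ATR	HOMDEL	any	ONCOKB	1	PARP inhibitor
ATR	HOMDEL	any	ESCAT	II	PARP inhibitor
MRE11	LOF_SNV	any	ONCOKB	1	PARP inhibitor
MRE11	LOF_SNV	any	ESCAT	II	PARP inhibitor
MRE11	HOMDEL	any	ONCOKB	1	PARP inhibitor
MRE11	HOMDEL	any	ESCAT	II	PARP inhibitor
MSI	MSI	somatic	ONCOKB	1	pembrolizumab
MSI	MSI	somatic	ESCAT	I	pembrolizumab
PTEN	LOF_SNV	somatic	ONCOKB	3B	AKT inhibitor
PTEN	HOMDEL	somatic	ONCOKB	3B	AKT inhibitor
PTEN	LOF_SNV	somatic	ESCAT	II	AKT inhibitor
PTEN	HOMDEL	somatic	ESCAT	II	AKT inhibitor
PIK3CA	LOF_SNV	somatic	ONCOKB	3B	AKT inhibitor
PIK3CA	LOF_SNV	somatic	ESCAT	III	AKT inhibitor
AKT1	LOF_SNV	somatic	ONCOKB	3B	AKT inhibitor
AKT1	LOF_SNV	somatic	ESCAT	III	AKT inhibitor
BRAF	AMP	somatic	ONCOKB	4	MEK inhibitor
CDKN2A	HOMDEL	somatic	ONCOKB	4	CDK4/6 inhibitor
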