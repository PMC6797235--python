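gene	phenotype	mim_disorder	mim_gene	inheritance	typical_onset
BRCA1	Hereditary breast and ovarian cancer	604370	113705	AD	Adult
BRCA2	Hereditary breast and ovarian cancer	612555	600185	AD	Adult
TP53	Li-Fraumeni syndrome	151623	191170	AD	Child/adult
STK11	Peutz-Jeghers syndrome	175200	602216	AD	Child/adult
MLH1	Lynch syndrome	158320	120436	AD	Adult
MSH2	Lynch syndrome	120435	609309	AD	Adult
MSH6	Lynch syndrome	614350	600678	AD	Adult
PMS2	Lynch syndrome	614337	600259	AD	Adult
APC	Familial adenomatous polyposis	175100	611731	AD	Child/adult
MUTYH	MYH-associated polyposis	608456	604933	AR	Adult
BMPR1A	Juvenile polyposis syndrome	174900	601299	AD	Child/adult
SMAD4	Juvenile polyposis syndrome	174900	600993	AD	Child/adult
VHL	Von Hippel-Lindau syndrome	193300	608537	AD	Child/adult
MEN1	Multiple endocrine neoplasia type 1	131100	613733	AD	Child/adult
RET	Multiple endocrine neoplasia type 2	171400	164761	AD	Child/adult
PTEN	PTEN hamartoma tumor syndrome	153480	601728	AD	Child/adult
RB1	Retinoblastoma	180200	614041	AD	Child
SDHD	Hereditary paraganglioma-pheochromocytoma syndrome	168000	602690	AD	Child/adult
SDHAF2	Hereditary paraganglioma-pheochromocytoma syndrome	601650	613019	AD	Child/adult
SDHC	Hereditary paraganglioma-pheochromocytoma syndrome	605373	602413	AD	Child/adult
SDHB	Hereditary paraganglioma-pheochromocytoma syndrome	115310	185470	AD	Child/adult
TSC1	Tuberous sclerosis complex	191100	605284	AD	Child
TSC2	Tuberous sclerosis complex	613254	191092	AD	Child
WT1	WT1-related Wilms tumor	194070	607102	AD	Child
NF2	Neurofibromatosis type 2	101000	607379	AD	Child/adult
COL3A1	Ehlers-Danlos syndrome, vascular type	130050	120180	AD	Child/adult
FBN1	Marfan syndrome, Loeys-Dietz syndromes, familial thoracic aortic aneurysms and dissections	154700	134797	AD	Child/adult
TGFBR1	Loeys-Dietz syndrome	609192	190181	AD	Child/adult
TGFBR2	Loeys-Dietz syndrome	610168	190182	AD	Child/adult
SMAD3	Loeys-Dietz syndrome	613795	603109	AD	Child/adult
ACTA2	Familial thoracic aortic aneurysm and dissection	611788	102620	AD	Adult
MYH11	Familial thoracic aortic aneurysm and dissection	132900	160745	AD	Adult
MYBPC3	Hypertrophic cardiomyopathy, dilated cardiomyopathy	115197	600958	AD	Child/adult
MYH7	Hypertrophic cardiomyopathy, dilated cardiomyopathy	192600	160760	AD	Child/adult
TNNT2	Hypertrophic cardiomyopathy, dilated cardiomyopathy	601494	191045	AD	Child/adult
TNNI3	Hypertrophic cardiomyopathy, dilated cardiomyopathy	613690	191044	AD	Child/adult
TPM1	Hypertrophic cardiomyopathy, dilated cardiomyopathy	115196	191010	AD	Child/adult
MYL3	Hypertrophic cardiomyopathy	608751	160790	AD	Child/adult
ACTC1	Hypertrophic cardiomyopathy, dilated cardiomyopathy	612098	102540	AD	Child/adult
PRKAG2	Hypertrophic cardiomyopathy, Wolff-Parkinson-White syndrome	600858	602743	AD	Child/adult
GLA	Fabry disease	301500	300644	XL	Child/adult
MYL2	Hypertrophic cardiomyopathy	608758	160781	AD	Child/adult
LMNA	Dilated cardiomyopathy	115200	150330	AD	Adult
RYR2	Catecholaminergic polymorphic ventricular tachycardia	604772	180902	AD	Child/adult
PKP2	Arrhythmogenic right ventricular cardiomyopathy	609040	602861	AD	Child/adult
DSP	Arrhythmogenic right ventricular cardiomyopathy	604400	125647	AD	Child/adult
DSC2	Arrhythmogenic right ventricular cardiomyopathy	610476	125645	AD	Child/adult
TMEM43	Arrhythmogenic right ventricular cardiomyopathy	604400	612048	AD	Adult
DSG2	Arrhythmogenic right ventricular cardiomyopathy	610193	125671	AD	Child/adult
KCNQ1	Romano-Ward long-QT syndrome types 1, 2, 3, Brugada syndrome	192500	607542	AD	Child/adult
KCNH2	Romano-Ward long-QT syndrome types 1, 2, 3, Brugada syndrome	613688	152427	AD	Child/adult
SCN5A	Romano-Ward long-QT syndrome types 1, 2, 3, Brugada syndrome	603830	600163	AD	Child/adult
LDLR	Familial hypercholesterolemia	143890	606945	AD	Child/adult
APOB	Familial hypercholesterolemia	603776	107730	AD	Child/adult
PCSK9	Familial hypercholesterolemia	603776	607786	AD	Child/adult
RYR1	Malignant hyperthermia susceptibility	145600	180901	AD	Child/adult
CACNA1S	Malignant hyperthermia susceptibility	601887	114208	AD	Child/adult
ATP7B	Wilson disease	277900	606882	AR	Child/adult
OTC	Ornithine transcarbamylase deficiency	311250	300461	XL	Newborn/child
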