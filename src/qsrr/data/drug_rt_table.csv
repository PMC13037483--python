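index,name,rt_exp_min,category,mw,xlogp3,hbd,partition
1,Fenfluramine,0.96,Stimulant/appetite suppressant,231.26,3.4,1,train
2,Nicotine,1.01,Stimulant/nicotinic alkaloid,162.23,1.17,0,train
3,Mexiletine,1.04,Antiarrhythmic/local anesthetic,179.26,2.2,1,train
4,Fencamfamin,1.18,Stimulant/central nervous system stimulant,215.33,3.8,0,train
5,Methylphenidate,1.21,Stimulant (ADHD medication),233.30,2.4,1,train
6,Clobutinol,1.23,Antitussive/cough suppressant,257.37,3.5,1,train
7,Caffeine,1.26,Stimulant/xanthine alkaloid,194.19,-0.07,0,train
8,Prilocaine,1.27,Local anesthetic,220.31,2.1,1,train
9,Fluoxetine,1.28,Antidepressant (SSRI),309.33,4.05,1,train
10,Fluvoxamine,1.29,Antidepressant (SSRI),318.33,3.2,1,train
11,Melperone,1.3,Antipsychotic (butyrophenone),263.38,3.1,0,train
12,Orphenadrine,1.33,Antihistamine/anticholinergic,269.38,3.7,0,train
13,Nortramadol,1.35,Opioid metabolite/analgesic,249.35,2.4,2,train
14,Cyclizine,1.38,Antihistamine/antiemetic,266.38,2.7,0,train
15,Venlafaxine,1.42,Antidepressant (SNRI),277.40,2.9,1,train
16,Normethadone,1.43,Opioid metabolite,295.42,3.7,0,train
17,Methadone,1.46,Opioid/narcotic analgesic,309.45,3.9,0,train
18,Nomifensine,1.47,Antidepressant (withdrawn),238.33,2.8,1,train
19,Cocaine,1.51,Stimulant/narcotic (local anesthetic),303.35,2.3,0,train
20,Imipramine,1.52,Antidepressant (TCA),280.41,4.8,0,train
21,Doxepin,1.53,Antidepressant (TCA)/antihistamine,279.38,4.3,0,train
22,Nordoxepin,1.54,Metabolite/antidepressant,265.35,3.9,1,train
23,Normianserine,1.54,Antidepressant metabolite,264.36,3.5,1,train
24,Biperiden,1.56,Anticholinergic/antiparkinsonian,311.50,4.2,1,train
25,Bupivacaine,1.57,Local anesthetic,288.43,3.4,1,train
26,Trimeprazine,1.58,Antihistamine/antipsychotic,298.45,4.1,0,train
27,Carbamazepine,1.59,Anticonvulsant/mood stabilizer,236.27,2.7,1,train
28,Promazine,1.6,Antipsychotic (phenothiazine),284.42,4.5,0,train
29,Maprotiline,1.61,Antidepressant (tetracyclic),277.40,4.4,1,train
30,Phenytoin,1.62,Anticonvulsant,252.27,2.5,2,train
31,Milnacipran,1.63,Antidepressant (SNRI),274.40,2.8,2,train
32,Codeine,1.64,Opioid/narcotic analgesic,299.36,1.14,1,train
33,Clomipramine,1.67,Antidepressant (TCA),314.85,5.2,0,train
34,Norcitalopram,1.68,Metabolite/antidepressant,306.40,3.8,1,train
35,Norclomipramine,1.69,Metabolite/antidepressant,300.83,4.9,1,train
36,Dibenzepin,1.7,Antidepressant (TCA),295.42,3.6,0,train
37,Tizanidine,1.71,Muscle relaxant/alpha-2 agonist,253.71,1.9,1,train
38,Molindone,1.72,Antipsychotic (indole derivative),276.37,2.6,1,train
39,Chlorpromazine,1.73,Antipsychotic (phenothiazine),318.86,5.4,0,train
40,Nordazepam,1.74,Benzodiazepine metabolite,270.72,3.1,1,train
41,Chlordiazepoxide,1.75,Benzodiazepine/anxiolytic,299.75,2.5,1,train
42,Norlevomepromazine,1.77,Metabolite/antipsychotic,330.88,5.0,1,train
43,Chloroquine,1.79,Antimalarial/immunomodulator,319.87,5.1,1,train
44,Metoclopramide,1.81,Antiemetic/prokinetic,299.80,2.0,2,train
45,Cinchocaine,1.85,Local anesthetic,343.46,4.6,1,train
46,Fentanyl,1.86,Opioid/narcotic (potent analgesic),336.47,4.0,0,train
47,Zolpidem,1.9,Sedative-hypnotic (imidazopyridine),307.39,2.5,0,train
48,Moperone,1.91,Antipsychotic (butyrophenone),355.44,3.8,0,train
49,Clozapine,1.92,Antipsychotic (atypical),326.82,3.7,1,train
50,Doxapram,1.93,Respiratory stimulant,378.51,3.9,0,train
51,Hydroxychloroquine,1.94,Antimalarial/immunomodulator,335.87,4.0,2,train
52,Diltiazem,1.96,Calcium channel blocker/antihypertensive,414.52,3.1,1,train
53,Haloperidol,1.97,Antipsychotic (butyrophenone),375.86,4.3,1,train
54,Zaleplon,2.0,Sedative-hypnotic (pyrazolopyrimidine),305.33,1.9,0,train
55,Cinnarizine,2.03,Antihistamine/antivertigo,368.51,5.8,0,train
56,Zopiclone,2.04,Sedative-hypnotic (cyclopyrrolone),388.81,1.5,0,train
57,Thioridazine,2.06,Antipsychotic (phenothiazine),370.58,5.9,0,train
58,Noscapine,2.08,Antitussive/opioid-related,413.42,2.6,0,train
59,Quetiapine,2.13,Antipsychotic (atypical),383.51,2.9,1,train
60,Buspirone,2.16,Anxiolytic (non-benzodiazepine),385.50,2.63,0,train
61,Selegiline,1.05,MAO-B inhibitor/antiparkinsonian,187.30,2.8,0,test
62,Ketamine,1.28,Dissociative anesthetic/hallucinogen,237.73,2.2,0,test
63,Tramadol,1.33,Opioid/analgesic (weak),263.38,2.6,1,test
64,Mepivacaine,1.41,Local anesthetic,246.35,2.3,1,test
65,Propranolol,1.47,Beta-blocker/antihypertensive,259.34,3.0,2,test
66,Amitriptyline,1.5,Antidepressant (TCA),277.40,4.9,0,test
67,Mirtazapine,1.54,Antidepressant (tetracyclic),265.35,3.0,1,test
68,Pentazocine,1.56,Opioid analgesic (mixed agonist-antagonist),285.42,3.3,1,test
69,Bisoprolol,1.6,Beta-blocker/antihypertensive,325.44,2.3,2,test
70,Citalopram,1.66,Antidepressant (SSRI),324.39,3.5,0,test
71,Diazepam,1.69,Benzodiazepine/anxiolytic-sedative,284.74,2.8,0,test
72,Disopyramide,1.74,Antiarrhythmic,339.48,3.1,1,test
73,Flumazenil,1.76,Benzodiazepine antagonist,303.28,1.1,1,test
74,Trimethoprim,1.78,Antimicrobial/antibiotic,290.32,0.91,2,test
75,Hydroxyzine,1.92,Antihistamine/anxiolytic-sedative,374.91,3.5,0,test
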