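# Clinical cohort: differentiation of liver tumor in 20 subjects.
# Histopathology codes: HCC hepatocellular carcinoma, PDA poorly
# differentiated adenocarcinoma, MDA moderately differentiated
# adenocarcinoma, CCC cholangiocellular carcinoma, SRCC signet ring cell
# carcinoma, SCC small-cell carcinoma, SqCC squamous cell carcinoma,
# IM insufficient material. tumor_size_mm: "A x B" in millimetres.
subject,gender,age,tumor_size_mm,histopathology,diagnosis
1,Male,45,109 x 127,"HCC, PDA",Hepatocellular carcinoma
2,Female,64,100 x 85,MDA,Metastasis gallbladder cancer
3,Female,69,26 x 24,PDA,Metastasis colon cancer
4,Female,74,30 x 30,PDA,Metastasis. Unknown source
5,Male,60,41 x 38,IM,Metastasis kidney cancer
6,Female,67,42 x 43,PDA,Metastasis caecum cancer
7,Male,68,94 x 62,MDA,Metastasis colon cancer
8,Male,58,67 x 65,IM,Metastasis pancreatic cancer
9,Female,77,40 x 45,PDA,Metastasis pancreatic cancer
10,Female,67,74 x 73,"CCC, MDA",Cholangiocellular carcinoma
11,Female,78,38 x 45,SRCC,Metastasis stomach cancer
12,Female,70,47 x 50,MDA,Metastasis pancreatic cancer
13,Male,60,51 x 52,SCC,Metastasis small bowel carcinoid
14,Male,58,14 x 17,MDA,Metastasis pancreatic cancer
15,Male,66,46 x 43,SqCC,Metastasis of unknown origin
16,Male,77,46 x 38,SCC,Metastasis pancreatic cancer
17,Male,74,28 x 30,PDA,Metastasis caecum cancer
18,Male,54,45 x 38,SCC,Metastasis small bowel carcinoid
19,Male,73,50 x 40,IM,Metastasis pancreatic cancer
20,Female,54,80 x 90,SqCC,Metastasis cervical cancer
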