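icd_version,icd_code,phecode,description,exclusion_low,exclusion_high
9,332.0,332,Parkinson's disease,330,337.9
10,G20,332,Parkinson's disease,330,337.9
9,333.0,333.1,Other degenerative diseases of the basal ganglia,330,337.9
10,G23.9,333.1,Other degenerative diseases of the basal ganglia,330,337.9
9,555.0,555.1,Regional enteritis (Crohn's disease),555,564.9
9,555.9,555.1,Regional enteritis (Crohn's disease),555,564.9
10,K50.0,555.1,Regional enteritis (Crohn's disease),555,564.9
10,K50.9,555.1,Regional enteritis (Crohn's disease),555,564.9
10,K50.1,555.21,Crohn's disease of large intestine,555,564.9
9,556.0,556,Ulcerative colitis,555,564.9
9,556.9,556,Ulcerative colitis,555,564.9
10,K51.0,556,Ulcerative colitis,555,564.9
10,K51.9,556,Ulcerative colitis,555,564.9
9,250.00,250.2,Type 2 diabetes,249,250.99
10,E11.9,250.2,Type 2 diabetes,249,250.99
9,272.0,272.11,Hypercholesterolemia,272,272.99
10,E78.0,272.11,Hypercholesterolemia,272,272.99
9,280.0,280.1,Iron deficiency anemia,280,285.99
10,D50.9,280.1,Iron deficiency anemia,280,285.99
9,290.0,290.1,Dementias,290,294.99
10,F03,290.1,Dementias,290,294.99
9,296.2,296.22,Major depressive disorder,296,296.99
10,F32.9,296.22,Major depressive disorder,296,296.99
9,300.00,300.1,Anxiety disorders,300,300.99
10,F41.9,300.1,Anxiety disorders,300,300.99
9,340.0,335,Multiple sclerosis,330,337.9
10,G35,335,Multiple sclerosis,330,337.9
9,346.9,340,Migraine,340,340.99
10,G43.9,340,Migraine,340,340.99
9,401.1,401.1,Essential hypertension,401,405.99
10,I10,401.1,Essential hypertension,401,405.99
9,410.9,411.2,Myocardial infarction,410,414.99
10,I21.9,411.2,Myocardial infarction,410,414.99
9,427.31,427.21,Atrial fibrillation,426,427.99
10,I48.91,427.21,Atrial fibrillation,426,427.99
9,428.0,428.2,Heart failure,428,428.99
10,I50.9,428.2,Heart failure,428,428.99
9,493.90,495,Asthma,490,498.99
10,J45.909,495,Asthma,490,498.99
9,530.81,530.11,GERD,530,530.99
10,K21.9,530.11,GERD,530,530.99
9,535.5,535,Gastritis and duodenitis,530.2,537.99
10,K29.7,535,Gastritis and duodenitis,530.2,537.99
9,564.0,563,Constipation,555,564.9
10,K59.00,563,Constipation,555,564.9
9,564.1,564.1,Irritable bowel syndrome,555,564.9
10,K58.9,564.1,Irritable bowel syndrome,555,564.9
9,571.5,571.5,Other chronic nonalcoholic liver disease,571,573.99
10,K76.0,571.5,Other chronic nonalcoholic liver disease,571,573.99
9,691.8,939,Atopic dermatitis,939,939.99
10,L20.9,939,Atopic dermatitis,939,939.99
9,696.1,696.4,Psoriasis,696,696.99
10,L40.9,696.4,Psoriasis,696,696.99
9,714.0,714.1,Rheumatoid arthritis,714,714.99
10,M06.9,714.1,Rheumatoid arthritis,714,714.99
9,715.9,740.1,Osteoarthritis,740,740.99
10,M19.90,740.1,Osteoarthritis,740,740.99
9,780.52,327.4,Insomnia,327,327.99
10,G47.00,327.4,Insomnia,327,327.99
9,244.9,244.4,Hypothyroidism,240,246.99
10,E03.9,244.4,Hypothyroidism,240,246.99
9,274.9,274.1,Gout,274,274.99
10,M10.9,274.1,Gout,274,274.99
9,278.00,278.1,Obesity,278,278.99
10,E66.9,278.1,Obesity,278,278.99
9,357.0,357,Inflammatory polyneuropathy,356,357.99
10,G61.0,357,Inflammatory polyneuropathy,356,357.99
9,579.0,557.1,Celiac disease,555,564.9
10,K90.0,557.1,Celiac disease,555,564.9
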