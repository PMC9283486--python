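low	high	chapter
001	139	Infectious And Parasitic Diseases
140	239	Neoplasms
240	279	Endocrine, Nutritional And Metabolic Diseases, And Immunity Disorders
280	289	Diseases Of The Blood And Blood-Forming Organs
290	319	Mental Disorders
320	389	Diseases Of The Nervous System And Sense Organs
390	459	Diseases Of The Circulatory System
460	519	Diseases Of The Respiratory System
520	579	Diseases Of The Digestive System
580	629	Diseases Of The Genitourinary System
630	679	Complications Of Pregnancy, Childbirth, And The Puerperium
680	709	Diseases Of The Skin And Subcutaneous Tissue
710	739	Diseases Of The Musculoskeletal System And Connective Tissue
740	759	Congenital Anomalies
760	779	Certain Conditions Originating In The Perinatal Period
780	799	Symptoms, Signs, And Ill-Defined Conditions
800	999	Injury And Poisoning
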