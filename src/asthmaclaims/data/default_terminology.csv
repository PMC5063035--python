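code,dialect,class_label,human_name
R03AC02,DISPENSATION_FR_LIKE,SABA,salbutamol inhaler
R03AC03,DISPENSATION_FR_LIKE,SABA,terbutaline inhaler
R03AC12,DISPENSATION_FR_LIKE,LABA_MONO,salmeterol inhaler
R03AC13,DISPENSATION_FR_LIKE,LABA_MONO,formoterol inhaler
R03BA01,DISPENSATION_FR_LIKE,ICS_MONO,beclometasone inhaler
R03BA02,DISPENSATION_FR_LIKE,ICS_MONO,budesonide inhaler
R03BA05,DISPENSATION_FR_LIKE,ICS_MONO,fluticasone inhaler
R03AK06,DISPENSATION_FR_LIKE,FDC_ICS_LABA,salmeterol/fluticasone combination
R03AK07,DISPENSATION_FR_LIKE,FDC_ICS_LABA,formoterol/budesonide combination
R03DC01,DISPENSATION_FR_LIKE,LTRA,zafirlukast tablets
R03DC03,DISPENSATION_FR_LIKE,LTRA,montelukast tablets
R03DA04,DISPENSATION_FR_LIKE,XANTHINE,theophylline tablets
R03DA05,DISPENSATION_FR_LIKE,XANTHINE,aminophylline tablets
H02AB04,DISPENSATION_FR_LIKE,OCS,methylprednisolone tablets
H02AB06,DISPENSATION_FR_LIKE,OCS,prednisolone tablets
H02AB07,DISPENSATION_FR_LIKE,OCS,prednisone tablets
R03DX05,DISPENSATION_FR_LIKE,OMALIZUMAB,omalizumab injection
R03DX05X,DISPENSATION_FR_LIKE,OMALIZUMAB,omalizumab injection (hospital pack)
R03BB04,DISPENSATION_FR_LIKE,TIOTROPIUM,tiotropium inhaler
R03BB54,DISPENSATION_FR_LIKE,TIOTROPIUM,tiotropium inhaler (refill kit)
R03AC18,DISPENSATION_FR_LIKE,INDACATEROL,indacaterol inhaler
R03AC63,DISPENSATION_FR_LIKE,INDACATEROL,indacaterol combination inhaler
J44,DISPENSATION_FR_LIKE,COPD,chronic obstructive pulmonary disease
J449,DISPENSATION_FR_LIKE,COPD,"COPD, unspecified"
E84,DISPENSATION_FR_LIKE,CYSTIC_FIBROSIS,cystic fibrosis
E840,DISPENSATION_FR_LIKE,CYSTIC_FIBROSIS,cystic fibrosis with pulmonary manifestations
C34,DISPENSATION_FR_LIKE,LUNG_CANCER,malignant neoplasm of bronchus and lung
C349,DISPENSATION_FR_LIKE,LUNG_CANCER,"lung cancer, unspecified site"
J47,DISPENSATION_FR_LIKE,BRONCHIECTASIS,bronchiectasis
J470,DISPENSATION_FR_LIKE,BRONCHIECTASIS,bronchiectasis with acute infection
A15,DISPENSATION_FR_LIKE,TUBERCULOSIS,respiratory tuberculosis
A162,DISPENSATION_FR_LIKE,TUBERCULOSIS,tuberculosis of lung
D86,DISPENSATION_FR_LIKE,SARCOIDOSIS,sarcoidosis
D869,DISPENSATION_FR_LIKE,SARCOIDOSIS,"sarcoidosis, unspecified"
J45,DISPENSATION_FR_LIKE,ASTHMA,asthma
J459,DISPENSATION_FR_LIKE,ASTHMA,"asthma, unspecified"
c11a1,PRESCRIPTION_UK_LIKE,SABA,salbutamol 100mcg inhaler
c11b2,PRESCRIPTION_UK_LIKE,SABA,terbutaline 500mcg inhaler
c31a1,PRESCRIPTION_UK_LIKE,LABA_MONO,salmeterol 25mcg inhaler
c31b1,PRESCRIPTION_UK_LIKE,LABA_MONO,formoterol 12mcg inhaler
c61a1,PRESCRIPTION_UK_LIKE,ICS_MONO,beclometasone 100mcg inhaler
c61b1,PRESCRIPTION_UK_LIKE,ICS_MONO,budesonide 200mcg inhaler
c61c1,PRESCRIPTION_UK_LIKE,ICS_MONO,fluticasone 125mcg inhaler
c71a1,PRESCRIPTION_UK_LIKE,FDC_ICS_LABA,salmeterol/fluticasone combination inhaler
c71b1,PRESCRIPTION_UK_LIKE,FDC_ICS_LABA,formoterol/budesonide combination inhaler
c81a1,PRESCRIPTION_UK_LIKE,LTRA,montelukast 10mg tablets
c81b1,PRESCRIPTION_UK_LIKE,LTRA,zafirlukast 20mg tablets
c51a1,PRESCRIPTION_UK_LIKE,XANTHINE,theophylline m/r tablets
c51b1,PRESCRIPTION_UK_LIKE,XANTHINE,aminophylline m/r tablets
fe61a,PRESCRIPTION_UK_LIKE,OCS,prednisolone 5mg tablets
fe62a,PRESCRIPTION_UK_LIKE,OCS,prednisone 5mg tablets
c91x1,PRESCRIPTION_UK_LIKE,OMALIZUMAB,omalizumab injection
c91x2,PRESCRIPTION_UK_LIKE,OMALIZUMAB,omalizumab pre-filled syringe
c41t1,PRESCRIPTION_UK_LIKE,TIOTROPIUM,tiotropium 18mcg capsules
c41t2,PRESCRIPTION_UK_LIKE,TIOTROPIUM,tiotropium respimat inhaler
c41i1,PRESCRIPTION_UK_LIKE,INDACATEROL,indacaterol 150mcg capsules
c41i2,PRESCRIPTION_UK_LIKE,INDACATEROL,indacaterol 300mcg capsules
H33..,PRESCRIPTION_UK_LIKE,ASTHMA,asthma
H331.,PRESCRIPTION_UK_LIKE,ASTHMA,intrinsic asthma
H32..,PRESCRIPTION_UK_LIKE,COPD,chronic obstructive pulmonary disease
H3z..,PRESCRIPTION_UK_LIKE,COPD,chronic obstructive airways disease NOS
C370.,PRESCRIPTION_UK_LIKE,CYSTIC_FIBROSIS,cystic fibrosis
C3701,PRESCRIPTION_UK_LIKE,CYSTIC_FIBROSIS,cystic fibrosis with pulmonary manifestations
B221.,PRESCRIPTION_UK_LIKE,LUNG_CANCER,malignant neoplasm of lung
B22z.,PRESCRIPTION_UK_LIKE,LUNG_CANCER,malignant neoplasm of bronchus NOS
H34..,PRESCRIPTION_UK_LIKE,BRONCHIECTASIS,bronchiectasis
H340.,PRESCRIPTION_UK_LIKE,BRONCHIECTASIS,recurrent bronchiectasis
A115.,PRESCRIPTION_UK_LIKE,TUBERCULOSIS,pulmonary tuberculosis
A11z.,PRESCRIPTION_UK_LIKE,TUBERCULOSIS,pulmonary tuberculosis NOS
D860.,PRESCRIPTION_UK_LIKE,SARCOIDOSIS,sarcoidosis of lung
D86z.,PRESCRIPTION_UK_LIKE,SARCOIDOSIS,sarcoidosis NOS
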