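variant,standard,category
EEG Fpz-Cz,EEG Fpz-Cz,EEG
EEG Pz-Oz,EEG Pz-Oz,EEG
EEG C4-A1,EEG C4-A1,EEG
EEG C3-A2,EEG C3-A2,EEG
EEG O2-A1,EEG O2-A1,EEG
EEG O1-A2,EEG O1-A2,EEG
EEG F4-A1,EEG F4-A1,EEG
EEG F3-A2,EEG F3-A2,EEG
EEGC4-A1,EEG C4-A1,EEG
C4-A1,EEG C4-A1,EEG
C4A1,EEG C4-A1,EEG
C3A2,EEG C3-A2,EEG
EOG horizontal,EOG horizontal,EOG
EOG E1-M2,EOG E1-M2,EOG
EOG E2-M1,EOG E2-M1,EOG
LOC,EOG E1-M2,EOG
ROC,EOG E2-M1,EOG
EMG submental,EMG submental,EMG
EMG Chin,EMG submental,EMG
CHIN1,EMG submental,EMG
EMG LAT,EMG LAT,EMG
EMG RAT,EMG RAT,EMG
LEGBEINLI,EMG LAT,EMG
LEGBEINRE,EMG RAT,EMG
Bein li,EMG LAT,EMG
Bein re,EMG RAT,EMG
ECG I,ECG I,ECG
EKG,ECG I,ECG
EKG1,ECG I,ECG
Resp nasal,Resp nasal,Resp
Resp thoracic,Resp thoracic,Resp
Resp abdominal,Resp abdominal,Resp
AIRFLOW,Resp nasal,Resp
FLOW,Resp nasal,Resp
THOR RES,Resp thoracic,Resp
ABDO RES,Resp abdominal,Resp
SaO2,SaO2,SaO2
SPO2,SaO2,SaO2
Snore,Snore,Sound
SCHNARCHEN,Snore,Sound
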