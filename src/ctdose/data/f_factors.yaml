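# Protocol-specific effective-dose conversion coefficients f [mSv/(mGy·cm)]
# for adult CT, per AAPM Report No. 96 (Task Group 23).  ED = DLP × f.
head: 0.0021
neck: 0.0059
chest: 0.014
abdomen: 0.015
pelvis: 0.015
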