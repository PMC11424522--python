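# Published back-substitution test: full-data (actual) vs subsample-refitted (fitted) P50
# per sex, measure and age, with the per-row printed signed relative error.
sex,measure,age,actual_p50,fitted_p50,printed_error
male,height,12,149.72,150.00,0.00
male,height,13,158.62,159.50,-0.01
male,height,14,164.74,165.00,0.00
male,height,15,166.11,165.00,0.01
male,height,16,167.79,168.00,0.00
female,height,12,152.16,152.00,0.00
female,height,13,157.87,159.00,-0.01
female,height,14,161.68,162.00,0.00
female,height,15,162.38,162.00,0.00
female,height,16,162.65,162.00,0.00
male,weight,12,37.38,35.90,0.04
male,weight,13,41.79,41.50,0.01
male,weight,14,45.28,45.23,0.00
male,weight,15,47.58,47.00,0.01
male,weight,16,49.68,49.00,0.01
female,weight,12,35.70,33.85,0.05
female,weight,13,37.73,36.00,0.05
female,weight,14,40.93,41.00,0.00
female,weight,15,44.02,43.00,0.02
female,weight,16,44.12,43.50,0.01
male,bmi,12,16.59,16.45,0.01
male,bmi,13,16.81,16.54,0.02
male,bmi,14,17.03,17.19,-0.01
male,bmi,15,17.26,16.70,0.03
male,bmi,16,17.48,17.15,0.02
female,bmi,12,15.26,14.67,0.04
female,bmi,13,15.71,15.82,-0.01
female,bmi,14,15.73,15.60,0.01
female,bmi,15,16.74,16.36,0.02
female,bmi,16,16.81,16.52,0.02
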