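# Published P50 medians from external reference standards (heights cm, weights kg, BMI kg/m^2).
# Cells a source does not publish (WHO weight) are simply absent.
source,sex,age,measure,p50
WHO,male,12,height,149.1
WHO,male,13,height,156.0
WHO,male,14,height,163.2
WHO,male,15,height,169.0
WHO,male,16,height,172.9
WHO,female,12,height,151.2
WHO,female,13,height,156.4
WHO,female,14,height,159.8
WHO,female,15,height,161.7
WHO,female,16,height,162.5
WHO,male,12,bmi,17.5
WHO,male,13,bmi,18.2
WHO,male,14,bmi,19.0
WHO,male,15,bmi,19.8
WHO,male,16,bmi,20.5
WHO,female,12,bmi,18.0
WHO,female,13,bmi,18.8
WHO,female,14,bmi,19.6
WHO,female,15,bmi,20.2
WHO,female,16,bmi,20.7
US-CDC,male,12,height,153.4
US-CDC,male,13,height,164.5
US-CDC,male,14,height,169.5
US-CDC,male,15,height,173.7
US-CDC,male,16,height,175.4
US-CDC,female,12,height,156.7
US-CDC,female,13,height,159.5
US-CDC,female,14,height,161.9
US-CDC,female,15,height,161.7
US-CDC,female,16,height,161.4
US-CDC,male,12,weight,49.2
US-CDC,male,13,weight,56.6
US-CDC,male,14,weight,60.4
US-CDC,male,15,weight,66.0
US-CDC,male,16,weight,70.7
US-CDC,female,12,weight,51.4
US-CDC,female,13,weight,52.3
US-CDC,female,14,weight,59.0
US-CDC,female,15,weight,59.5
US-CDC,female,16,weight,58.7
US-CDC,male,12,bmi,19.9
US-CDC,male,13,bmi,20.4
US-CDC,male,14,bmi,21.0
US-CDC,male,15,bmi,21.5
US-CDC,male,16,bmi,22.7
US-CDC,female,12,bmi,20.6
US-CDC,female,13,bmi,20.9
US-CDC,female,14,bmi,22.4
US-CDC,female,15,bmi,22.1
US-CDC,female,16,bmi,22.1
India,male,12,height,150.2
India,male,13,height,156.1
India,male,14,height,161.5
India,male,15,height,165.9
India,male,16,height,169.3
India,female,12,height,149.8
India,female,13,height,153.3
India,female,14,height,155.6
India,female,15,height,156.9
India,female,16,height,157.7
India,male,12,weight,41.0
India,male,13,weight,45.5
India,male,14,weight,50.1
India,male,15,weight,54.4
India,male,16,weight,58.5
India,female,12,weight,41.9
India,female,13,weight,45.5
India,female,14,weight,48.4
India,female,15,weight,50.8
India,female,16,weight,52.6
India,male,12,bmi,18.1
India,male,13,bmi,18.6
India,male,14,bmi,19.2
India,male,15,bmi,19.8
India,male,16,bmi,20.3
India,female,12,bmi,18.7
India,female,13,bmi,19.4
India,female,14,bmi,20.0
India,female,15,bmi,20.6
India,female,16,bmi,21.1
Turkey,male,12,height,150.6
Turkey,male,13,height,157.7
Turkey,male,14,height,164.9
Turkey,male,15,height,170.3
Turkey,male,16,height,173.4
Turkey,female,12,height,153.1
Turkey,female,13,height,157.8
Turkey,female,14,height,160.4
Turkey,female,15,height,161.7
Turkey,female,16,height,162.4
Turkey,male,12,weight,44.3
Turkey,male,13,weight,49.8
Turkey,male,14,weight,56.2
Turkey,male,15,weight,62.1
Turkey,male,16,weight,66.2
Turkey,female,12,weight,45.1
Turkey,female,13,weight,50.0
Turkey,female,14,weight,53.3
Turkey,female,15,weight,55.3
Turkey,female,16,weight,56.3
Turkey,male,12,bmi,19.3
Turkey,male,13,bmi,19.9
Turkey,male,14,bmi,20.5
Turkey,male,15,bmi,21.2
Turkey,male,16,bmi,21.9
Turkey,female,12,bmi,19.0
Turkey,female,13,bmi,19.9
Turkey,female,14,bmi,20.6
Turkey,female,15,bmi,21.0
Turkey,female,16,bmi,21.2
China,male,12,height,151.9
China,male,13,height,159.5
China,male,14,height,165.9
China,male,15,height,169.8
China,male,16,height,171.6
China,female,12,height,152.4
China,female,13,height,156.3
China,female,14,height,158.6
China,female,15,height,159.8
China,female,16,height,160.1
China,male,12,weight,42.5
China,male,13,weight,48.1
China,male,14,weight,53.4
China,male,15,weight,57.9
China,male,16,weight,59.4
China,female,12,weight,40.8
China,female,13,weight,44.8
China,female,14,weight,47.8
China,female,15,weight,49.8
China,female,16,weight,50.8
China,male,12,bmi,18.1
China,male,13,bmi,18.7
China,male,14,bmi,19.2
China,male,15,bmi,19.7
China,male,16,bmi,20.1
China,female,12,bmi,17.5
China,female,13,bmi,18.2
China,female,14,bmi,18.8
China,female,15,bmi,19.3
China,female,16,bmi,19.7
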