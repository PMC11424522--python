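# Published age- and sex-specific LMS growth reference, South Punjab adolescents (2019 survey).
# Height/weight rows carry P3,P10,P35,P50,P65,P90; BMI rows carry P5,P15,P50,P85,P90,P95.
sex,age_group,measure,n,lam,mu,sigma,P3,P5,P10,P15,P35,P50,P65,P85,P90,P95
male,12,height,,3.020,149.72,0.069,126.98,,135.08,,145.63,149.72,153.60,,161.93,
male,13,height,,5.231,158.62,0.062,132.49,,143.13,,154.63,158.62,162.23,,169.52,
male,14,height,,6.000,164.74,0.055,140.16,,150.31,,161.05,164.74,168.06,,174.72,
male,15,height,,5.021,166.11,0.049,146.77,,154.04,,162.85,166.11,169.13,,175.43,
male,16,height,,4.931,167.79,0.042,151.81,,157.61,,164.99,167.79,170.42,,176.00,
female,12,height,,5.344,152.16,0.060,128.00,,137.81,,148.45,152.16,155.51,,162.29,
female,13,height,,4.770,157.87,0.055,136.89,,144.87,,154.39,157.87,161.09,,167.76,
female,14,height,,4.924,161.68,0.045,144.91,,151.07,,158.78,161.68,164.39,,170.10,
female,15,height,,4.759,162.38,0.043,146.62,,152.32,,159.60,162.38,164.99,,170.53,
female,16,height,,4.179,162.65,0.045,146.52,,152.26,,159.75,162.65,165.39,,171.28,
male,12,weight,,0.531,37.38,0.246,21.98,,26.47,,33.92,37.38,41.00,,50.03,
male,13,weight,,0.368,41.79,0.214,27.03,,31.29,,38.44,41.79,45.32,,54.27,
male,14,weight,,0.205,45.28,0.179,31.94,,35.80,,42.24,45.28,48.49,,56.66,
male,15,weight,,0.042,47.58,0.165,34.81,,38.47,,44.65,47.58,50.70,,58.73,
male,16,weight,,-0.122,49.68,0.167,36.50,,40.22,,46.60,49.68,52.99,,61.72,
female,12,weight,,0.301,35.70,0.226,22.65,,26.36,,32.69,35.70,38.90,,47.13,
female,13,weight,,0.158,37.73,0.180,26.64,,29.83,,35.19,37.73,40.42,,47.33,
female,14,weight,,0.062,40.93,0.179,29.13,,32.48,,38.20,40.93,43.84,,51.40,
female,15,weight,,0.202,44.02,0.165,31.95,,35.46,,41.29,44.02,46.29,,51.53,
female,16,weight,,0.515,44.12,0.126,34.27,,37.27,,42.00,44.12,46.89,,54.15,
male,12,bmi,,0.203,16.59,0.141,,13.08,,14.32,,16.59,,19.14,19.81,20.81
male,13,bmi,,-0.318,16.81,0.131,,13.65,,14.73,,16.81,,19.30,19.98,21.01
male,14,bmi,,-0.838,17.03,0.125,,14.09,,15.07,,17.03,,19.52,20.23,21.34
male,15,bmi,,-1.358,17.26,0.124,,14.42,,15.34,,17.26,,19.86,20.64,21.92
male,16,bmi,,-1.879,17.48,0.125,,14.69,,15.58,,17.48,,20.26,21.15,22.67
female,12,bmi,,0.283,15.26,0.202,,11.08,,12.68,,15.26,,18.27,19.11,20.33
female,13,bmi,,-0.173,15.71,0.172,,11.58,,12.82,,15.71,,18.85,19.52,20.40
female,14,bmi,,-0.495,15.73,0.168,,12.14,,13.32,,15.73,,18.97,19.75,21.17
female,15,bmi,,-0.234,16.74,0.159,,12.99,,14.25,,16.74,,19.23,20.17,21.58
female,16,bmi,,0.382,16.81,0.120,,13.69,,14.81,,16.81,,19.78,20.63,21.93
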