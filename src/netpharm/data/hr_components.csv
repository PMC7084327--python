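id,name,MW,AlogP,nHdon,nHacc,TPSA,RBN,OB,Caco2,DL,GI
HR01,Aloe-emodin,270.25,1.67,3,5,94.83,,83.38,-0.12,0.24,High
HR02,alpha-Boswellic acid,456.78,6.42,2,3,57.53,,39.32,0.6,0.75,Low
HR03,Anthraquinone,208.22,2.81,0,2,34.14,,56.1,0.86,0.14,High
HR04,beta-Boswellic acid,456.78,6.47,2,3,57.53,,39.55,0.59,0.75,Low
HR05,Chrysophanol,254.25,2.76,2,4,74.6,,18.64,0.62,0.21,High
HR06,Colchicine,385.45,1.47,2,7,94.09,,39.34,0.12,0.57,High
HR07,Hemerocallone,356.35,2.59,0,7,76.36,,63.01,0.77,0.54,High
HR08,Kaempferol,286.25,1.77,4,6,111.13,,41.88,0.26,0.24,High
HR09,Puerarin,416.41,-0.06,6,9,160.82,,24.03,-1.15,0.69,High
HR10,Rhein,284.23,1.88,3,6,111.9,,47.07,-0.2,0.28,High
HR11,Vanillic acid,168.16,1.15,2,4,66.76,,35.47,0.43,0.04,High
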