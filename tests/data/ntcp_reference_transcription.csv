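# Independent second transcription of the published NTCP parameter
# tables (double-entry guard against transcription error in the
# packaged YAML library).  p1 = n (LKB) or gamma (RS); p2 = D50 in Gy;
# p3 = m (LKB) or s (RS).
organ,model,source,variant,endpoint,p1,p2,p3,note
heart,LKB,Emami/Burman,,pericarditis,0.35,48.00,0.10,whole heart
heart,LKB,Martel,,pericarditis,0.636,50.60,0.13,pericard (1cm thick shell)
heart,RS,Emami/Agren-Cronqvist,,pericarditis,3,49.20,0.2,whole heart
heart,RS,Gagliardi,,excess cardiac mortality,1.28,52.40,1.00,whole heart
heart,RS,Eriksson,a,excess cardiac mortality,0.93,63.30,1.00,whole heart
heart,RS,Eriksson,b,excess cardiac mortality,0.96,70.30,1.00,whole heart
lung,LKB,Emami/Burman,,pneumonitis,0.87,24.50,0.18,
lung,LKB,Kwa,,pneumonitis,1.00,30.50,0.30,
lung,LKB,Seppenwoolde,,pneumonitis,0.99,30.80,0.37,
lung,LKB,De Jaeger,EPL,pneumonitis,1.00,34.10,0.45,parameters derived from equivalent-pathlength dose calculations
lung,LKB,De Jaeger,CS,pneumonitis,1.00,29.20,0.45,parameters derived from convolution-superposition dose calculations
lung,RS,Emami/Agren-Cronqvist,,pneumonitis,2.10,24.50,0.0061,
lung,RS,Seppenwoolde,,pneumonitis,0.900,34.00,0.060,
lung,RS,Gagliardi,,pneumonitis,0.966,30.10,0.012,lungs were considered as separate organs
parotid,LKB,Emami/Burman,,total xerostomia,0.70,46.00,0.18,total xerostomia
parotid,LKB,Eisbruch,,25% xerostomia,1.00,28.40,0.18,25% xerostomia at 1 year
parotid,LKB,Roesink,,25% xerostomia,1.00,39.00,0.45,25% xerostomia at 1 year
rectum,LKB,Rancati,a,late rectal bleeding,0.23,81.90,0.19,solid rectum including filling
rectum,LKB,Rancati,b,late rectal bleeding,0.06,78.60,0.06,solid rectum including filling
rectum,LKB,Tucker,,late rectal bleeding,0.08,78.00,0.14,solid rectum including filling
rectum,LKB,Peeters,,late rectal bleeding,0.13,80.70,0.14,rectal wall
rectum,LKB,Soehn,,late rectal bleeding,0.08,78.40,0.11,rectal wall
rectum,LKB,Rancati,c,late rectal bleeding,0.085,97.70,0.27,solid rectum including filling
rectum,RS,Rancati,,late rectal bleeding,1.69,83.10,0.49,solid rectum including filling
femoral_head,LKB,Emami/Burman,,necrosis,0.25,65.00,0.12,
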