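gene,class,dataset,logFC,adj_p,present
KRT1,squamous,GSE13083,-7.49126,1.11e-05,1
KRT1,squamous,GSE34619,-3.3024845,1.10e-03,1
KRT1,squamous,GSE1420,-2.217323,0.277797,1
KRT4,squamous,GSE13083,-4.6401743,5.80e-02,1
KRT4,squamous,GSE34619,-5.428193,2.16e-05,1
KRT4,squamous,GSE1420,0.9627934,0.291337,1
KRT5,squamous,GSE13083,-6.9473657,1.02e-02,1
KRT5,squamous,GSE34619,-5.19733,1.27e-05,1
KRT5,squamous,GSE1420,0.2659335,0.939807,1
KRT6,squamous,GSE13083,-5.0172743,3.66e-02,1
KRT6,squamous,GSE34619,-4.5273685,7.31e-05,1
KRT6,squamous,GSE1420,0.3930203,0.885997,1
KRT10,squamous,GSE13083,-1.9265443,4.80e-03,1
KRT10,squamous,GSE34619,-1.9039765,1.43e-02,1
KRT10,squamous,GSE1420,0.0731168,0.925068,1
KRT13,squamous,GSE13083,-5.3344986,4.04e-02,1
KRT13,squamous,GSE34619,-5.5419725,5.55e-05,1
KRT13,squamous,GSE1420,0.4701058,0.861817,1
KRT14,squamous,GSE13083,-4.0982471,1.17e-01,1
KRT14,squamous,GSE34619,-2.2296553,1.88e-03,1
KRT14,squamous,GSE1420,1.928972,0.499067,1
KRT15,squamous,GSE13083,-6.05938,2.09e-03,1
KRT15,squamous,GSE34619,-4.686177,2.79e-10,1
KRT15,squamous,GSE1420,-0.327417,0.941066,1
KRT16,squamous,GSE13083,-5.0731586,5.63e-03,1
KRT16,squamous,GSE34619,-3.5205307,2.61e-05,1
KRT16,squamous,GSE1420,1.16582,0.682918,1
KRT17,squamous,GSE13083,-2.6745814,8.21e-02,1
KRT17,squamous,GSE34619,-1.7824035,1.42e-03,1
KRT17,squamous,GSE1420,2.6061311,0.297826,1
KRT23,squamous,GSE13083,-2.0889186,3.74e-02,1
KRT23,squamous,GSE34619,-1.2800192,7.70e-02,1
KRT23,squamous,GSE1420,0.0060589,0.997257,1
KRT24,squamous,GSE13083,-4.4806771,2.26e-03,1
KRT24,squamous,GSE34619,-2.905637,7.73e-05,1
KRT24,squamous,GSE1420,-0.676433,0.81305,1
KRT7,columnar,GSE13083,2.2155471,4.07e-02,1
KRT7,columnar,GSE34619,1.9065172,5.46e-06,1
KRT7,columnar,GSE1420,1.6998427,0.204673,1
KRT8,columnar,GSE13083,6.4172871,2.18e-09,1
KRT8,columnar,GSE34619,4.0091988,3.50e-11,1
KRT8,columnar,GSE1420,2.6806701,0.027973,1
KRT18,columnar,GSE13083,3.4490243,5.03e-06,1
KRT18,columnar,GSE34619,2.024285,2.16e-06,1
KRT18,columnar,GSE1420,1.9282774,0.082523,1
KRT19,columnar,GSE13083,1.7536714,1.01e-03,1
KRT19,columnar,GSE34619,0.759105,3.08e-02,1
KRT19,columnar,GSE1420,1.2141959,0.658343,1
KRT20,columnar,GSE13083,8.5259443,3.44e-09,1
KRT20,columnar,GSE34619,4.374532,2.00e-04,1
KRT20,columnar,GSE1420,4.8072071,0.037302,1
TFF1,columnar,GSE13083,8.2017486,1.75e-05,1
TFF1,columnar,GSE34619,6.4595337,1.46e-12,1
TFF1,columnar,GSE1420,5.6843253,0.010407,1
TFF2,columnar,GSE13083,7.6665729,4.86e-05,1
TFF2,columnar,GSE34619,5.2354248,1.23e-08,1
TFF2,columnar,GSE1420,5.8714482,0.006909,1
TFF3,columnar,GSE13083,8.9897857,9.11e-08,1
TFF3,columnar,GSE34619,2.2346355,2.20e-04,1
TFF3,columnar,GSE1420,3.3738183,0.110978,1
VIL1,columnar,GSE13083,5.8340643,8.63e-09,1
VIL1,columnar,GSE34619,2.2711873,1.88e-08,1
VIL1,columnar,GSE1420,2.5215122,0.025483,1
MUC1,columnar,GSE13083,1.5493643,1.21e-01,1
MUC1,columnar,GSE34619,1.9449625,1.69e-05,1
MUC1,columnar,GSE1420,1.1435938,0.427828,1
MUC2,columnar,GSE13083,6.7226214,3.16e-06,1
MUC2,columnar,GSE34619,2.1981597,2.77e-03,1
MUC2,columnar,GSE1420,2.9508572,0.271622,1
MUC3A/B,columnar,GSE13083,0.7757457,9.80e-02,1
MUC3A/B,columnar,GSE34619,4.3127432,6.68e-09,1
MUC3A/B,columnar,GSE1420,0.9212935,0.225325,1
MUC4,columnar,GSE13083,-1.07354,1.13e-01,1
MUC4,columnar,GSE34619,0.1271057,8.92e-01,1
MUC4,columnar,GSE1420,1.903752,0.360547,1
MUC5AC,columnar,GSE13083,8.1766871,8.25e-07,1
MUC5AC,columnar,GSE34619,,,0
MUC5AC,columnar,GSE1420,7.1466461,0.005318,1
MUC5B,columnar,GSE13083,2.7593857,4.75e-02,1
MUC5B,columnar,GSE34619,1.6075105,2.00e-03,1
MUC5B,columnar,GSE1420,2.3107749,0.510519,1
MUC6,columnar,GSE13083,3.1026371,7.45e-03,1
MUC6,columnar,GSE34619,5.9384813,1.46e-11,1
MUC6,columnar,GSE1420,3.4098322,0.017934,1
MUC12,columnar,GSE13083,,,0
MUC12,columnar,GSE34619,2.2172345,1.33e-03,1
MUC12,columnar,GSE1420,,,0
MUC13,columnar,GSE13083,7.3541829,5.65e-10,1
MUC13,columnar,GSE34619,7.3474513,1.87e-11,1
MUC13,columnar,GSE1420,3.6273263,0.031468,1
MUC15,columnar,GSE13083,,,0
MUC15,columnar,GSE34619,-4.7653307,4.28e-10,1
MUC15,columnar,GSE1420,,,0
MUC17,columnar,GSE13083,,,0
MUC17,columnar,GSE34619,5.953779,6.32e-08,1
MUC17,columnar,GSE1420,,,0
MUC21,columnar,GSE13083,,,0
MUC21,columnar,GSE34619,-5.732196,5.46e-07,1
MUC21,columnar,GSE1420,,,0
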