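{
 "threshold_table": {
  "identities": [
   50,
   55,
   60,
   65,
   70,
   75,
   80,
   85,
   90,
   95,
   100
  ],
  "coverages": [
   0,
   10,
   20,
   30,
   40,
   50,
   60,
   70,
   80,
   90,
   100
  ],
  "thresholds": [
   [
    0.1527777777777778,
    0.4697986577181208,
    0.4727272727272727,
    0.45982142857142855,
    0.4423963133640553,
    0.43312101910828027,
    0.41735537190082644,
    0.4083044982698962,
    0.4182692307692308,
    0.45318352059925093,
    0.0
   ],
   [
    0.16433566433566432,
    0.5182724252491694,
    0.5081967213114754,
    0.4892086330935252,
    0.4666666666666667,
    0.45318352059925093,
    0.4388059701492537,
    0.424,
    0.4280936454849498,
    0.45714285714285713,
    0.0
   ],
   [
    0.16532258064516128,
    0.5588235294117647,
    0.5416666666666666,
    0.5220588235294118,
    0.5035460992907801,
    0.483695652173913,
    0.4594594594594595,
    0.4439252336448598,
    0.45318352059925093,
    0.46458923512747874,
    0.0
   ],
   [
    0.1830065359477124,
    0.5941558441558441,
    0.5720338983050848,
    0.5480225988700564,
    0.5220588235294118,
    0.5026178010471204,
    0.47854785478547857,
    0.46551724137931033,
    0.46900269541778977,
    0.4831081081081081,
    0.0
   ],
   [
    0.18385650224215247,
    0.6319018404907976,
    0.6063348416289592,
    0.5822102425876011,
    0.5566037735849056,
    0.5339805825242718,
    0.5119047619047619,
    0.5,
    0.5,
    0.5213675213675214,
    0.0
   ],
   [
    0.21782178217821782,
    0.6956521739130435,
    0.6626984126984127,
    0.6330532212885154,
    0.6071428571428571,
    0.579185520361991,
    0.5568181818181818,
    0.5476190476190477,
    0.5387323943661971,
    0.5416666666666666,
    0.0
   ],
   [
    0.21777777777777776,
    0.7705627705627706,
    0.729957805907173,
    0.6966824644549763,
    0.6567656765676567,
    0.6222222222222222,
    0.5991902834008097,
    0.5957446808510638,
    0.5951417004048583,
    0.6189024390243902,
    0.0
   ],
   [
    0.31333333333333335,
    0.8636363636363636,
    0.8207547169811321,
    0.7910863509749304,
    0.7444794952681388,
    0.6984732824427481,
    0.6679841897233202,
    0.6966824644549763,
    0.6648351648351648,
    0.6966824644549763,
    0.0
   ],
   [
    0.2864583333333333,
    1.057057057057057,
    1.00920245398773,
    0.952755905511811,
    0.89375,
    0.84375,
    0.8184713375796179,
    0.8249027237354085,
    0.7717041800643086,
    0.8184713375796179,
    0.0
   ],
   [
    0.47959183673469385,
    1.3229571984435797,
    1.2731277533039647,
    1.236842105263158,
    1.1976047904191616,
    1.1083333333333334,
    1.0934065934065933,
    1.0555555555555556,
    1.0521172638436482,
    0.9901960784313726,
    0.0
   ],
   [
    0.2553191489361702,
    1.6216216216216217,
    1.8109756097560976,
    2.497584541062802,
    3.0774647887323945,
    3.95,
    4.98581560283688,
    4.98581560283688,
    4.95483870967742,
    0.0,
    0.0
   ]
  ]
 },
 "identity_score_map": {
  "slope": 6.061295260664483,
  "intercept": -0.8452890934522299
 },
 "meta": {
  "n_pairs": 200000,
  "seed": 42
 }
}
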