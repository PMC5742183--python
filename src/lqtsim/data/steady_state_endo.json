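{
 "variant": "endocardial",
 "pacing": {
  "cycle_length_ms": 1000.0,
  "pre_beats": 3000
 },
 "biomarkers": {
  "apd90_ms": 268.16745723143686,
  "apd50_ms": 208.2494807470357,
  "ca_dia_uM": 0.0852129727630898,
  "ca_sys_uM": 0.3572849122344516,
  "na_max_mM": 7.235757312134076
 },
 "state": {
  "v": -87.92781325980788,
  "nai": 7.230490991080831,
  "nass": 7.2305750737614005,
  "ki": 144.26362362428233,
  "kss": 144.26359715459975,
  "cai": 8.525071836624832e-05,
  "cass": 8.414743151075758e-05,
  "cansr": 1.6052029617507466,
  "cajsr": 1.5592828648461925,
  "m": 0.007399044709463215,
  "hf": 0.6955352532616252,
  "hs": 0.6955184276926166,
  "j": 0.6954243363429988,
  "hsp": 0.4519346226351875,
  "jp": 0.6953612695394412,
  "mL": 0.00019092980193773806,
  "hL": 0.4989891667636899,
  "hLp": 0.2681718022509607,
  "a": 0.0010061099277940265,
  "iF": 0.9995483584756198,
  "iS": 0.5907781671031886,
  "ap": 0.000512641426820718,
  "iFp": 0.9995483658876427,
  "iSp": 0.643331644774973,
  "d": 2.3821536353361404e-09,
  "ff": 0.9999999906900486,
  "fs": 0.9108112729987237,
  "fcaf": 0.9999999906901113,
  "fcas": 0.9998219818920954,
  "jca": 0.999976960865524,
  "nca": 0.002653662751816576,
  "ffp": 0.999999990687147,
  "fcafp": 0.9999999906873218,
  "xrf": 8.160026918743769e-06,
  "xrs": 0.4515176107819612,
  "xs1": 0.27012235726342576,
  "xs2": 0.00019445337912441372,
  "xk1": 0.9967791600262859,
  "Jrelnp": 2.4750847011222025e-07,
  "Jrelp": 3.0922484785075403e-07,
  "CaMKt": 0.012269603336463989
 }
}
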