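{
 "variant": "epicardial",
 "pacing": {
  "cycle_length_ms": 1000.0,
  "pre_beats": 3000
 },
 "biomarkers": {
  "apd90_ms": 228.28757178015076,
  "apd50_ms": 182.67560986767057,
  "ca_dia_uM": 0.07542193179304678,
  "ca_sys_uM": 0.6489810522230293,
  "na_max_mM": 7.80206890894403
 },
 "state": {
  "v": -87.76811368811748,
  "nai": 7.794705621901573,
  "nass": 7.794785978999063,
  "ki": 143.0934340199288,
  "kss": 143.09340201433318,
  "cai": 7.544955603701607e-05,
  "cass": 7.446729601892197e-05,
  "cansr": 1.9652594171901758,
  "cajsr": 1.9094974977291166,
  "m": 0.007518816648109817,
  "hf": 0.6899501850208325,
  "hs": 0.6899399124631168,
  "j": 0.6898808716215699,
  "hsp": 0.4454680165642959,
  "jp": 0.68983956521032,
  "mL": 0.00019680980060375687,
  "hL": 0.4964393819370333,
  "hLp": 0.27164118533281256,
  "a": 0.0010169973028571549,
  "iF": 0.9995356125715203,
  "iS": 0.9995272123707273,
  "ap": 0.000518191621844634,
  "iFp": 0.9995356128995416,
  "iSp": 0.9995337972641042,
  "d": 2.4737948718309585e-09,
  "ff": 0.9999999902796949,
  "fs": 0.922377134978959,
  "fcaf": 0.9999999902797357,
  "fcas": 0.9998888679503478,
  "jca": 0.9999843554354352,
  "nca": 0.0016595049455673419,
  "ffp": 0.9999999902778305,
  "fcafp": 0.9999999902779454,
  "xrf": 8.322789118580131e-06,
  "xrs": 0.42611022758103845,
  "xs1": 0.24270181806323046,
  "xs2": 0.0001979373983934483,
  "xk1": 0.9968204825717477,
  "Jrelnp": 4.696304591765032e-07,
  "Jrelp": 5.869236137365755e-07,
  "CaMKt": 0.015453612745352058
 }
}
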