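{
 "dataset":{
  "0":"dataset0",
  "1":"dataset1",
  "2":"dataset2"
 },
 "n_stress_responsive":{
  "0":16,
  "1":32,
  "2":27
 },
 "n_g9a_dependent":{
  "0":4,
  "1":5,
  "2":4
 },
 "pct_g9a_dependent":{
  "0":25,
  "1":15,
  "2":14
 }
}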