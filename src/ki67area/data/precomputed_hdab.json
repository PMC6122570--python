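{
 "centroids": [
  [
   253.40735535862197,
   253.41569379530154,
   253.4121095890657
  ],
  [
   159.77481539057607,
   119.9064904780247,
   114.87889623010128
  ],
  [
   142.8543016194041,
   136.13952429147787,
   197.4431680162032
  ]
 ],
 "roles": [
  "background",
  "dab",
  "hematoxylin"
 ],
 "transform": [
  [
   0.0,
   -0.033156270050323275,
   0.9994501797270087
  ],
  [
   0.0,
   -0.9994501797270087,
   -0.033156270050323275
  ],
  [
   1.0,
   0.0,
   0.0
  ]
 ],
 "projection_axis": [
  0.0,
  -0.033156270050323275,
  0.9994501797270087
 ],
 "presence_threshold": -11.542001427804923
}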