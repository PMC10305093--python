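version: matched-demo-0.1
source: Synthetic demo algorithm derived from the cohort generator's class-conditional
  item model; stands in for the published short-algorithm coefficients, which are
  not distributed here.
form: logistic
intercept: 12.011599645474563
coefficients:
  cogscore: -1.9352717508502575
  relscore: 2.1931008601523576
  cerad: -1.7176514970743333
  eurod: 0.8873031950009029
threshold: 0.4527979204797713
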