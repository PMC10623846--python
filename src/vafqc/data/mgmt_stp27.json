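{
  "model": "MGMT-STP27",
  "version": "1.0",
  "description": "Published logistic model predicting MGMT promoter methylation from the M-values of EPIC/450K probes cg12434587 and cg12981137 (mgmtstp27 R package).",
  "intercept": 4.3215,
  "coef_cg12434587": 0.5271,
  "coef_cg12981137": 0.9265,
  "prob_cutoff": 0.358,
  "equivocal_halfwidth": 0.0
}
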