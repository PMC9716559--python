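{
 "format": "regval-classifier",
 "version": 1,
 "feature_names": [
  "accuracy",
  "fp_rate",
  "smooth_sensitivity",
  "smooth_wrmsd",
  "z_accuracy",
  "z_sensitivity",
  "z_wrmsd",
  "acc",
  "ss_helix",
  "ss_sheet",
  "ss_coil"
 ],
 "scaler": {
  "mean": [
   0.9584211353877484,
   0.008495562831790338,
   0.07026011523816868,
   2.7162591324573744,
   0.18642687646508313,
   -0.09730148785791709,
   0.19508329575088715,
   0.12580152671755726,
   0.8694656488549618,
   0.0,
   0.13053435114503817
  ],
  "scale": [
   0.029350286722471204,
   0.010846443924522085,
   0.08396271149829042,
   1.2188115087614908,
   0.8995024907569574,
   0.7949122987966997,
   0.9437989081956554,
   0.15747993546482358,
   0.3368903891715851,
   1.0,
   0.3368903891715851
  ]
 },
 "svm": {
  "coef": [
   -0.20961207732681028,
   -0.05021676506748077,
   -0.052336736297134756,
   1.021878161607979,
   0.24053112106296373,
   0.0031694572370388665,
   0.23679685021926355,
   -0.08417880961167098,
   -0.04659515922320274,
   0.0,
   0.04659515922320237
  ],
  "intercept": 0.12181524839159502
 },
 "calibration": {
  "a": 3.5081802445407115,
  "b": 0.01964576303781634
 },
 "metadata": {
  "seed": 1,
  "n_iter": 200,
  "cv": 5,
  "n_train": 1310,
  "best_params": {
   "C": 0.021515294012389465,
   "class_weight": null
  },
  "cv_accuracy": 0.8923664122137405,
  "training_data": "synthetic labelled dataset (40 helix-bundle chains, defaults), seed 1",
  "holdout_auc": 0.9807,
  "holdout_accuracy": 0.7059
 }
}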