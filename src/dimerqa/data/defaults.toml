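# dimerqa default cutoff/weight profile.
#
# Decision thresholds (ipTM and C2Qscore cutoffs, DockQ class bounds, the
# ipTM gray zone) are the published per-method values.  The regression
# weights/bias are NOT published numbers: they were refit once on this
# package's synthetic benchmark (calibration module, seed 20250926) and are
# shipped as editable data — replace them with externally fitted weights for
# real predictor output.

dockq_class_bounds = [0.23, 0.49, 0.80]

[gray_zone]
low = 0.6
high = 0.8

[cf-t]
bias = -0.3729
ipae_max = 31.75

[cf-t.weights]
iplddt = 0.2697
ipae = 1.1272
ptm = -0.4838
iptm = 0.3161
voroif = -0.068

[cf-t.cutoffs]
iptm = 0.65
c2qscore = 0.55

[cf-f]
bias = -0.3897
ipae_max = 31.75

[cf-f.weights]
iplddt = 0.3937
ipae = 0.6522
ptm = 0.2437
iptm = -0.2343
voroif = 0.1165

[cf-f.cutoffs]
iptm = 0.65
c2qscore = 0.48

[af3]
bias = -0.1311
ipae_max = 31.75

[af3.weights]
iplddt = -0.2386
ipae = 0.6907
ptm = 0.2109
iptm = -0.1078
voroif = 0.3197

[af3.cutoffs]
iptm = 0.70
c2qscore = 0.52
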