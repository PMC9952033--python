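"""Run a small end-to-end benchmark: simulate, denoise, extract, classify.

Generates 60 labeled phantoms at sigma = 20 (default 55% malignant
composition), denoises each, extracts the 24-feature bank, fits Gaussian
naive Bayes on a stratified 80% split and scores the held-out 20%.
Accuracy / specificity / sensitivity follow the usual confusion-matrix
definitions with "malignant" as the positive class.
"""

from lungnlb.benchmark import run_benchmark

report = run_benchmark(n=60, sigma=20.0, seed=7)

m = report["metrics"]
c = report["counts"]
print(f"train/test sizes : {report['n_train']}/{report['n_test']}")
print(f"confusion counts : tp={c.tp} tn={c.tn} fp={c.fp} fn={c.fn}")
print(f"accuracy         : {m.accuracy:.3f}")
print(f"specificity      : {m.specificity:.3f}")
print(f"sensitivity      : {m.sensitivity:.3f}")
print(f"mean PSNR gain   : {report['mean_psnr_gain_db']:.2f} dB over {report['n_phantoms']} phantoms")
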