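"""Reference descriptives of the original study's stimulus windows.

Per-window summary of the 12-min Italian narrative analysed in the
study this pipeline models: mean +/- sd context size in tokens and in
(full) words, mean +/- sd token surprisal after HRF convolution and
down-sampling, and the number of fMRI time points (out of 709) retained
for the saliency analysis.  These printed values serve as inputs for
calibration checks (the context-size vs. surprisal correlation, and the
valid-time-point arithmetic); the pipeline never fits to them.
"""

import pandas as pd

STUDY_WINDOW_SUMMARY = pd.DataFrame(
    {
        "window_s": [15, 30, 45, 60, 75, 90],
        "mean_tokens": [53.52, 105.62, 156.47, 206.1, 254.51, 301.59],
        "sd_tokens": [7.2, 15.36, 26.24, 39.17, 53.64, 69.23],
        "mean_words": [45.4, 89.55, 132.56, 174.61, 215.53, 255.32],
        "mean_surprisal": [3.76, 3.69, 3.8, 3.87, 3.93, 3.99],
        "n_valid_timepoints": [683, 668, 653, 638, 623, 608],
    }
)

N_VOLUMES = 709
N_TOKENS = 2512
N_WORDS = 1589
N_SUBJECTS = 27
N_ROIS = 1000
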