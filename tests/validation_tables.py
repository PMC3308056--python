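"""Published validation columns used by the metric-arithmetic tests.

Each entry: (label, TP, TN, FP, FN, expected printed percentages).
Expected values are the printed two-decimal percentages for sensitivity,
specificity, PPV, NPV, FPR, FDR, accuracy and MCC.
"""

COLUMNS = [
    # first cohort, standard base calls
    # (the published count row lists TN=72 for this column, but every printed
    # statistic - specificity 97.26 = 71/73, NPV 67.62 = 71/105, accuracy
    # 77.91 = 127/163, MCC 61.78 - follows exactly from TN=71; the count cell
    # is evidently a typo, so TN=71 is used here)
    ("snpseeker_illumina", 56, 71, 2, 34,
     dict(sensitivity=62.22, specificity=97.26, ppv=96.55, npv=67.62,
          fpr=2.74, fdr=3.45, accuracy=77.91, mcc=61.78)),
    ("samtools_illumina", 83, 41, 32, 7,
     dict(sensitivity=92.22, specificity=56.16, ppv=72.17, npv=85.42,
          fpr=43.84, fdr=27.83, accuracy=76.07, mcc=52.79)),
    ("crisp_illumina", 79, 44, 29, 11,
     dict(sensitivity=87.78, specificity=60.27, ppv=73.15, npv=80.00,
          fpr=39.73, fdr=26.85, accuracy=75.46, mcc=50.54)),
    ("syzygy_illumina", 85, 49, 24, 5,
     dict(sensitivity=94.44, specificity=67.12, ppv=77.98, npv=90.74,
          fpr=32.88, fdr=22.02, accuracy=82.21, mcc=65.05)),
    ("servic4e_illumina", 88, 62, 11, 2,
     dict(sensitivity=97.78, specificity=84.93, ppv=88.89, npv=96.88,
          fpr=15.07, fdr=11.11, accuracy=92.02, mcc=84.22)),
    # first cohort, model-based base calls
    ("samtools_srfim", 80, 60, 13, 10,
     dict(sensitivity=88.89, specificity=82.19, ppv=86.02, npv=85.71,
          fpr=17.81, fdr=13.98, accuracy=85.89, mcc=71.41)),
    ("crisp_srfim", 78, 50, 23, 12,
     dict(sensitivity=86.67, specificity=68.49, ppv=77.23, npv=80.65,
          fpr=31.51, fdr=22.77, accuracy=78.53, mcc=56.50)),
    ("syzygy_srfim", 80, 51, 22, 10,
     dict(sensitivity=88.89, specificity=69.86, ppv=78.43, npv=83.61,
          fpr=30.14, fdr=21.57, accuracy=80.37, mcc=60.37)),
    ("servic4e_srfim", 84, 61, 12, 6,
     dict(sensitivity=93.33, specificity=83.56, ppv=87.50, npv=91.04,
          fpr=16.44, fdr=12.50, accuracy=88.96, mcc=77.72)),
    # second cohort
    ("syzygy_cohort2", 47, 38, 26, 8,
     dict(sensitivity=85.45, specificity=59.38, ppv=64.38, npv=82.61,
          fpr=40.63, fdr=35.62, accuracy=71.43, mcc=45.90)),
    ("servic4e_cohort2", 53, 60, 4, 2,
     dict(sensitivity=96.36, specificity=93.75, ppv=92.98, npv=96.77,
          fpr=6.25, fdr=7.02, accuracy=94.96, mcc=89.93)),
]
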