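{
  "description": "Published summary statistics of a candidate-gene association study of obesity in 773 prepubertal school children (five SNPs in LEPR, FTO, MC4R and PPARG-2). Genotype counts and allele-frequency tables per weight-category group, per-genotype stratum means of BMI and zBMI, and the published effect-decomposition table. Printed values are stored as strings to preserve the published decimal precision.",
  "n_total": 773,
  "n_case": 233,
  "n_control": 540,
  "snps": {
    "rs1137101": {
      "gene": "LEPR",
      "major": "A",
      "minor": "G",
      "genotype_counts": {
        "overall": [190, 273, 154],
        "case": [52, 86, 33],
        "control": [115, 165, 105]
      },
      "allele_counts_printed": {
        "case": [190, 152],
        "control": [395, 375]
      },
      "strata": {
        "zbmi": {
          "major_homo": [[76, 2.11], [107, 0.15]],
          "het": [[127, 2.14], [138, 0.13]],
          "minor_homo": [[50, 2.07], [99, -0.05]]
        },
        "bmi": {
          "major_homo": [[76, 23.29], [107, 16.95]],
          "het": [[127, 23.58], [138, 16.89]],
          "minor_homo": [[50, 23.18], [99, 16.59]]
        }
      },
      "printed": {
        "allele_p": "0.189",
        "hwe": {"overall": "0.006", "case": "0.88", "control": "0.0058"},
        "effects": {
          "bmi": {"dominant": "0.52", "additive": "-0.43", "population_mean": "18.56", "minor_avg_effect": "-0.25", "aecme": "-0.48"},
          "zbmi": {"dominant": "0.28", "additive": "-0.15", "population_mean": "0.81", "minor_avg_effect": "-0.09", "aecme": "-0.17"}
        },
        "dominance_type": "overdominance",
        "effect_grade": "weak decrease"
      }
    },
    "rs9939609": {
      "gene": "FTO",
      "major": "T",
      "minor": "A",
      "genotype_counts": {
        "overall": [159, 259, 112],
        "case": [86, 137, 68],
        "control": [93, 160, 69]
      },
      "allele_counts_printed": {
        "case": [183, 151],
        "control": [346, 298]
      },
      "strata": {
        "zbmi": {
          "major_homo": [[86, 2.05], [69, 0.16]],
          "het": [[137, 2.04], [119, 0.24]],
          "minor_homo": [[68, 2.12], [42, 0.02]]
        },
        "bmi": {
          "major_homo": [[86, 22.81], [69, 16.85]],
          "het": [[137, 22.89], [119, 16.99]],
          "minor_homo": [[68, 23.24], [42, 16.56]]
        }
      },
      "printed": {
        "allele_p": "0.75",
        "hwe": {"overall": "0.73", "case": "0.88", "control": "1.00"},
        "effects": {
          "bmi": {"dominant": "-0.01", "additive": "0.12", "population_mean": "18.7", "minor_avg_effect": "0.06", "aecme": "0.12"},
          "zbmi": {"dominant": "-0.07", "additive": "0.06", "population_mean": "1.27", "minor_avg_effect": "0.03", "aecme": "0.06"}
        },
        "dominance_type": "complete_dominance",
        "effect_grade": "very weak increase"
      }
    },
    "rs2229616": {
      "gene": "MC4R",
      "major": "G",
      "minor": "A",
      "genotype_counts": {
        "overall": [428, 9, 0],
        "case": [120, 2, 0],
        "control": [275, 7, 0]
      },
      "allele_counts_printed": {
        "case": [242, 2],
        "control": [557, 7]
      },
      "strata": {
        "zbmi": {
          "major_homo": [[226, 2.15], [199, 0.04]],
          "het": [[5, 2.29], [4, -0.10]],
          "minor_homo": []
        },
        "bmi": {
          "major_homo": [[226, 23.40], [199, 16.59]],
          "het": [[5, 24.05], [4, 16.25]],
          "minor_homo": []
        }
      },
      "printed": {
        "allele_p": "0.600",
        "hwe": {"overall": "1.00", "case": "1.00", "control": "1.00"}
      }
    },
    "rs17782313": {
      "gene": "MC4R",
      "major": "T",
      "minor": "C",
      "genotype_counts": {
        "overall": [222, 110, 20],
        "case": [76, 34, 4],
        "control": [132, 66, 14]
      },
      "allele_counts_printed": {
        "case": [186, 42],
        "control": [330, 94]
      },
      "strata": {
        "zbmi": {
          "major_homo": [[140, 2.22], [80, 0.13]],
          "het": [[77, 2.03], [32, 0.11]],
          "minor_homo": [[15, 2.26], [4, 0.04]]
        },
        "bmi": {
          "major_homo": [[140, 23.92], [80, 16.74]],
          "het": [[77, 22.69], [32, 16.85]],
          "minor_homo": [[15, 23.89], [4, 16.55]]
        }
      },
      "printed": {
        "allele_p": "0.261",
        "hwe": {"overall": "0.2", "case": "1.00", "control": "0.16"},
        "effects": {
          "bmi": {"dominant": "0.05", "additive": "-0.54", "population_mean": "18.37", "minor_avg_effect": "-0.12", "aecme": "-0.57"},
          "zbmi": {"dominant": "-0.16", "additive": "0.17", "population_mean": "1.63", "minor_avg_effect": "0.06", "aecme": "0.26"}
        },
        "dominance_type": "complete_dominance",
        "effect_grade": "weak increase"
      }
    },
    "rs1801282": {
      "gene": "PPARG",
      "major": "C",
      "minor": "G",
      "genotype_counts": {
        "overall": [225, 45, 2],
        "case": [58, 15, 0],
        "control": [157, 28, 2]
      },
      "allele_counts_printed": {
        "case": [131, 15],
        "control": [342, 32]
      },
      "strata": {
        "zbmi": {
          "major_homo": [[64, 1.95], [140, 0.23]],
          "het": [[12, 1.79], [33, 0.02]],
          "minor_homo": [[2, 0.90]]
        },
        "bmi": {
          "major_homo": [[64, 22.04], [140, 16.82]],
          "het": [[12, 21.42], [33, 16.46]],
          "minor_homo": [[2, 17.87]]
        }
      },
      "printed": {
        "allele_p": "0.539",
        "hwe": {"overall": "1.00", "case": "1.00", "control": "0.63"},
        "effects": {
          "bmi": {"dominant": "1.45", "additive": "-1.15", "population_mean": "18.3", "minor_avg_effect": "-0.21", "aecme": "-2.34"},
          "zbmi": {"dominant": "0.68", "additive": "-1.12", "population_mean": "1.24", "minor_avg_effect": "-0.15", "aecme": "-1.68"}
        },
        "dominance_type": "partial_dominance",
        "effect_grade": "medium decrease",
        "caveat": "effect estimates rest on two minor homozygotes"
      }
    }
  }
}
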