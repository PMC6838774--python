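{
  "version": "1.0",
  "note": "Resting energy expenditure prediction equations. Inputs: W weight [kg], H height [cm], A age [years]. Output kcal/day unless unit says MJ/day (converted at 239.006 kcal/MJ).",
  "equations": {
    "harris_benedict": {
      "source": "Harris & Benedict 1919, as commonly rounded",
      "unit": "kcal/day",
      "male": {"intercept": 66.5, "weight": 13.75, "height_cm": 5.003, "age": -6.755},
      "female": {"intercept": 655.1, "weight": 9.563, "height_cm": 1.85, "age": -4.676}
    },
    "updated_harris_benedict": {
      "source": "Roza & Shizgal 1984 re-evaluation",
      "unit": "kcal/day",
      "male": {"intercept": 88.362, "weight": 13.397, "height_cm": 4.799, "age": -5.677},
      "female": {"intercept": 447.593, "weight": 9.247, "height_cm": 3.098, "age": -4.33}
    },
    "mifflin_st_jeor": {
      "source": "Mifflin et al. 1990",
      "unit": "kcal/day",
      "male": {"intercept": 5.0, "weight": 10.0, "height_cm": 6.25, "age": -5.0},
      "female": {"intercept": -161.0, "weight": 10.0, "height_cm": 6.25, "age": -5.0}
    },
    "mueller": {
      "source": "Mueller et al. 2004 (whole-sample equation)",
      "unit": "MJ/day",
      "male": {"intercept": 4.219, "weight": 0.047, "height_cm": 0.0, "age": -0.01452},
      "female": {"intercept": 3.21, "weight": 0.047, "height_cm": 0.0, "age": -0.01452}
    },
    "mueller_bmi": {
      "source": "Mueller et al. 2004 (BMI-class-specific equations); class coefficients must be supplied by the user from the primary source",
      "unit": "MJ/day",
      "bmi_classes": null
    }
  }
}
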