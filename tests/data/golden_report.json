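{
 "anchors": {
  "2mmol": {
   "histogram": {
    "10": 0,
    "11": 0,
    "12": 3,
    "13": 0,
    "14": 0,
    "15": 0,
    "16": 0,
    "17": 0,
    "18": 0,
    "19": 0,
    "20": 0,
    "6": 0,
    "7": 0,
    "8": 0,
    "9": 0
   },
   "median": 12.0,
   "missing": 1,
   "n": 3,
   "q1": 12.0,
   "q3": 12.0
  },
  "3mmol": {
   "histogram": {
    "10": 0,
    "11": 0,
    "12": 0,
    "13": 0,
    "14": 3,
    "15": 0,
    "16": 0,
    "17": 0,
    "18": 0,
    "19": 0,
    "20": 0,
    "6": 0,
    "7": 0,
    "8": 0,
    "9": 0
   },
   "median": 14.0,
   "missing": 1,
   "n": 3,
   "q1": 14.0,
   "q3": 14.0
  },
  "4mmol": {
   "histogram": {
    "10": 0,
    "11": 0,
    "12": 0,
    "13": 0,
    "14": 0,
    "15": 1,
    "16": 2,
    "17": 0,
    "18": 0,
    "19": 0,
    "20": 0,
    "6": 0,
    "7": 0,
    "8": 0,
    "9": 0
   },
   "median": 16.0,
   "missing": 1,
   "n": 3,
   "q1": 15.5,
   "q3": 16.0
  },
  "lt2": {
   "histogram": {
    "10": 0,
    "11": 0,
    "12": 0,
    "13": 0,
    "14": 3,
    "15": 0,
    "16": 0,
    "17": 0,
    "18": 0,
    "19": 0,
    "20": 0,
    "6": 0,
    "7": 0,
    "8": 0,
    "9": 0
   },
   "median": 14.0,
   "missing": 1,
   "n": 3,
   "q1": 14.0,
   "q3": 14.0
  }
 },
 "covariate_means": {
  "age": 37.75,
  "n_stages": 6.75,
  "vo2max": 41.75
 },
 "crossovers": {},
 "exclusions": {
  "counts": {
   "A_retest": 1,
   "B_missing_bla": 1,
   "C_missing_rpe": 1,
   "D_lt3_stages": 1,
   "E_other_ergometry": 1,
   "F_implausible": 1
  },
  "n_input": 10,
  "n_kept": 4
 },
 "fit_failures": {
  "2mmol": "fewer than two outcome categories",
  "3mmol": "fewer than two outcome categories",
  "4mmol": "fewer observations than parameters",
  "lt2": "fewer than two outcome categories"
 },
 "mean_lt2_bla": 2.933333,
 "models": {
  "2mmol": null,
  "3mmol": null,
  "4mmol": null,
  "lt2": null
 },
 "n_analyzed": 4,
 "n_lt1_missing": 1,
 "n_spline_skipped": 0
}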