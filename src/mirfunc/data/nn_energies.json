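{
  "version": "1.0",
  "comment": "Nearest-neighbor free-energy parameters at 37 C (kcal/mol). Stack keys are 'outer/inner' base pairs reading the outer pair 5'->3' on the top strand. Loop tables are initiation energies by number of unpaired bases; lengths beyond the table are extrapolated as E(max) + 1.75*RT*ln(n/max).",
  "temperature_C": 37,
  "min_loop": 3,
  "terminal_au": 0.5,
  "multiloop": {"a": 3.4, "b": 0.4, "c": 0.4},
  "stack": {
    "GC/GC": -3.26, "GC/CG": -3.42, "GC/AU": -2.35, "GC/UA": -2.24, "GC/GU": -1.5, "GC/UG": -2.5,
    "CG/GC": -2.36, "CG/CG": -3.26, "CG/AU": -2.11, "CG/UA": -2.08, "CG/GU": -1.4, "CG/UG": -2.1,
    "AU/GC": -2.08, "AU/CG": -2.24, "AU/AU": -0.93, "AU/UA": -1.1, "AU/GU": -0.6, "AU/UG": -1.4,
    "UA/GC": -2.11, "UA/CG": -2.35, "UA/AU": -1.33, "UA/UA": -0.93, "UA/GU": -1.0, "UA/UG": -1.3,
    "GU/GC": -2.1, "GU/CG": -2.5, "GU/AU": -1.3, "GU/UA": -1.4, "GU/GU": 0.5, "GU/UG": -0.5,
    "UG/GC": -1.4, "UG/CG": -1.5, "UG/AU": -1.0, "UG/UA": -0.6, "UG/GU": 1.3, "UG/UG": 0.5
  },
  "hairpin": {"3": 5.4, "4": 5.6, "5": 5.7, "6": 5.4, "7": 6.0, "8": 5.5, "9": 6.4},
  "bulge": {"1": 3.8, "2": 2.8, "3": 3.2, "4": 3.6, "5": 4.0, "6": 4.4},
  "internal": {"2": 1.5, "3": 1.6, "4": 1.7, "5": 2.0, "6": 2.2, "7": 2.3, "8": 2.4, "9": 2.5, "10": 2.6}
}
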