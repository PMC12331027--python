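{
  "comment": "Solanum crop parameter sets fitted from the Yunnan field trials, one per genotype and season. Units: tm/te/tu/b degC d; rue g/MJ; wmax/a_max fractions. Phenology (emergence/maturity, days after sowing) and actual farm yields (t/ha) from the same study region. reported_potential_yield is the potential tuber yield (t/ha) reported for each parameter set.",
  "dry_matter_fraction": 0.2,
  "base_temperature": 2.0,
  "seasons": {
    "spring": {
      "actual_yield": 19.6,
      "genotypes": {
        "Yunshu 401": {"wmax": 1.0, "tm": 243, "te": 1145, "a_max": 0.88, "tu": 988, "b": 426, "rue": 5.5,
                       "emergence_day": 47, "maturity_day": 170, "reported_potential_yield": 138.0},
        "Yunshu 505": {"wmax": 0.99, "tm": 99, "te": 1107, "a_max": 1.0, "tu": 1044, "b": 473, "rue": 4.4,
                       "emergence_day": 44, "maturity_day": 164, "reported_potential_yield": 147.0},
        "Cooperation 88": {"wmax": 1.0, "tm": 427, "te": 1304, "a_max": 0.89, "tu": 1258, "b": 394, "rue": 3.98,
                           "emergence_day": 42, "maturity_day": 184, "reported_potential_yield": 91.9}
      }
    },
    "autumn": {
      "actual_yield": 15.27,
      "genotypes": {
        "Yunshu 401": {"wmax": 0.77, "tm": 482, "te": 1040, "a_max": 0.96, "tu": 669, "b": 290, "rue": 2.9,
                       "emergence_day": 21, "maturity_day": 107, "reported_potential_yield": 35.23},
        "Yunshu 505": {"wmax": 1.0, "tm": 341, "te": 1014, "a_max": 0.91, "tu": 721, "b": 250, "rue": 2.8,
                       "emergence_day": 25, "maturity_day": 120, "reported_potential_yield": 46.67},
        "Cooperation 88": {"wmax": 1.0, "tm": 524, "te": 1028, "a_max": 0.87, "tu": 823, "b": 190, "rue": 3.7,
                           "emergence_day": 16, "maturity_day": 116, "reported_potential_yield": 53.95}
      }
    },
    "early_spring": {
      "actual_yield": 20.72,
      "genotypes": {
        "Yunshu 401": {"wmax": 0.7742, "tm": 200.1, "te": 956.4, "a_max": 0.9249, "tu": 544, "b": 150.1, "rue": 2.8,
                       "emergence_day": 34, "maturity_day": 123, "reported_potential_yield": 53.03},
        "Yunshu 505": {"wmax": 0.83, "tm": 112.7, "te": 898.5, "a_max": 0.99, "tu": 545.8, "b": 186.5, "rue": 2.63,
                       "emergence_day": 32, "maturity_day": 121, "reported_potential_yield": 62.78},
        "Cooperation 88": {"wmax": 0.8, "tm": 262, "te": 946, "a_max": 1.0, "tu": 532, "b": 386, "rue": 2.7,
                           "emergence_day": 35, "maturity_day": 122, "reported_potential_yield": 53.48}
      }
    }
  }
}
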