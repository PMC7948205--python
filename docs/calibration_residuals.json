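{
  "knobs": {
    "hepatocyte_mass": 1.82746,
    "small_pool_mass": 30.8946,
    "small_pool_exchange": 14.1782,
    "gut_emptying": 11.8313,
    "chylomicron_production": 19.7601,
    "dt_absorption": 0.199846,
    "chylomicron_clearance": 31.6649,
    "dt_remnant": 0.0810968,
    "mrt43": 0.173058,
    "mrt44": 0.120948
  },
  "landmarks": {
    "acute0_m5_day1": {
      "target": 0.76,
      "achieved": 0.8141562426067119,
      "weight": 1.5
    },
    "acute0_m5_nadir": {
      "target": 0.69,
      "achieved": 0.7134748760693166,
      "weight": 3.0
    },
    "acute0_m5_nadir_day": {
      "target": 2.0,
      "achieved": 2.1,
      "weight": 0.3
    },
    "acute0_m5_day5": {
      "target": 0.9,
      "achieved": 0.8252078160875926,
      "weight": 0.7
    },
    "acute0_f5_day1": {
      "target": 0.68,
      "achieved": 0.6516218488261923,
      "weight": 1.5
    },
    "acute0_f5_peak": {
      "target": 1.5,
      "achieved": 1.292613078592695,
      "weight": 1.5
    },
    "acute0_f5_peak_day": {
      "target": 6.0,
      "achieved": 5.3,
      "weight": 0.3
    },
    "acute0_sap_max": {
      "target": 1.6,
      "achieved": 1.5802839395937667,
      "weight": 2.5
    },
    "acute0_tbs_day1": {
      "target": 1.12,
      "achieved": 1.2494305463718,
      "weight": 0.5
    },
    "acute0_tbs_min": {
      "target": 0.63,
      "achieved": 0.6327976732188163,
      "weight": 4.0
    },
    "acute0_tbs_min_day": {
      "target": 5.0,
      "achieved": 4.4,
      "weight": 0.3
    },
    "acute0_share_min": {
      "target": 0.86,
      "achieved": 0.8515005943185013,
      "weight": 2.0
    },
    "acute3_tbs_min": {
      "target": 0.8,
      "achieved": 0.7583129030082216,
      "weight": 7.0
    },
    "chronic_m5_day10": {
      "target": 0.55,
      "achieved": 0.5330950332746631,
      "weight": 1.5
    },
    "chronic_tbs_day30": {
      "target": 1.1,
      "achieved": 1.0560853920082427,
      "weight": 4.0
    },
    "chronic_tbs_day1": {
      "target": 1.11,
      "achieved": 1.2976237569575968,
      "weight": 0.3
    },
    "chronic_tbs_min": {
      "target": 0.67,
      "achieved": 0.43546553457682896,
      "weight": 0.3
    }
  }
}
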