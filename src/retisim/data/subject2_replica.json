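{
  "absorption_efficiency": 0.74,
  "delay_times": {
    "DT(25)": 0.0810968,
    "DT(3)": 0.199846
  },
  "dietary_intake": 1.8918918918918914,
  "plasma_pool": 5.0,
  "rbp_residence": {
    "43": 0.173058,
    "44": 0.120948
  },
  "schema_version": 1,
  "subject_id": "subject-2-replica",
  "tbs_assigned": 980.0,
  "transfer_set": {
    "L(2,1)": 8.755162,
    "L(25,10)": 31.6649,
    "L(3,2)": 19.7601,
    "L(5,4)": 0.7660906394668007,
    "L(5,6)": 0.013301270374775114,
    "L(5,7)": 0.45892162384364904,
    "L(6,5)": 2.8,
    "L(7,5)": 2.83564,
    "L(9,6)": 0.0014779189305305681
  }
}
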