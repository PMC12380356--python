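{
  "_comment": "Synthetic reconstruction of the ten-node worked example's edge activation times. The topology (15 edges over V0..V9) is text-derived from the published base-cycle set; the activation times below are NOT read from the source figure but were reconstructed by constrained search so that the network reproduces every text-derivable property of the example (base-cycle sets and their time-5 subset, second-order neighbour sets, degree and score orderings). Replace this file to supply the true figure labels.",
  "edges": {
    "V0,V1": [2, 3, 9],
    "V0,V2": [0, 2],
    "V0,V7": [3, 5, 7, 8, 10],
    "V1,V3": [3, 5],
    "V2,V3": [5],
    "V2,V5": [5],
    "V2,V7": [2, 4],
    "V4,V6": [4],
    "V4,V7": [0, 4, 5, 7, 9],
    "V4,V8": [0, 3, 9],
    "V5,V6": [3, 4],
    "V6,V7": [3, 4],
    "V6,V8": [4],
    "V6,V9": [4],
    "V8,V9": [10]
  }
}
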