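{
  "n_full_spectrum_bands": 256,
  "colour_e": {
    "CARS": [397, 401, 404, 413, 418, 422, 432, 443, 498, 526, 541, 553, 621,
             623, 641, 717, 750, 972, 974, 993],
    "GA": [394, 397, 399, 401, 411, 413, 415, 420, 422, 425, 505, 507, 515,
           517, 519, 522, 524, 526, 529, 536, 538, 541, 543, 546, 548, 551,
           553, 555, 558],
    "SPA": [551, 392, 577]
  },
  "firmness": {
    "CARS": [394, 399, 406, 408, 411, 413, 415, 555, 616, 619, 626, 641, 643,
             678, 690, 693, 705, 707, 727, 730, 733, 743, 783, 785, 796, 974,
             987, 1022, 1024],
    "GA": [546, 548, 551, 553, 555, 558, 560, 675, 678, 680, 685, 688, 690,
           693, 698, 700, 703, 801, 1006, 1019, 1022, 1024],
    "SPA": [399, 406, 413, 415, 418, 422, 425, 429, 436, 439, 441, 448, 458,
            493, 510, 526, 546, 577, 648, 678, 695, 745, 875, 914, 945, 1019,
            1022]
  },
  "ssc": {
    "CARS": [418, 425, 439, 488, 505, 695, 705, 720, 824, 883, 885, 888, 914,
             919, 940, 961, 990, 1019],
    "GA": [418, 420, 462, 465, 467, 474, 476, 479, 484, 507, 522, 524, 901,
           904, 906, 917, 919, 982, 985, 987, 1016, 1019, 1022],
    "SPA": [406, 408, 418, 425, 432, 443, 446, 450, 453, 481, 775, 867, 914,
            937, 979, 1027]
  }
}
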