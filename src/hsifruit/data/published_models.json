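{
  "colour_e": {
    "intercept": 22.89,
    "terms": {
      "397": -8.82, "401": 12.37, "404": -22.02, "413": 28.37, "418": 2.09,
      "422": 20.83, "432": -11.90, "443": -24.50, "498": 23.75, "526": -17.75,
      "541": 20.45, "553": -16.34, "621": -0.04, "623": 21.10, "641": -8.06,
      "717": -15.07, "750": 14.64, "972": 23.98, "974": -0.96, "993": -18.62
    }
  },
  "firmness": {
    "intercept": 13.36,
    "terms": {
      "394": -11.57, "399": 19.69, "406": -14.56, "408": -21.74, "411": 11.40,
      "413": 21.95, "415": -1.14, "555": 5.08, "616": -72.32, "619": 98.67,
      "626": -48.77, "641": 8.86, "643": 5.32, "678": -1.30, "690": -31.62,
      "693": 53.08, "705": 22.26, "707": -61.38, "727": 100.76, "730": -95.06,
      "733": 48.17, "743": -11.88, "783": -9.22, "785": -23.11, "796": 10.39,
      "974": -15.85, "987": 1.51, "1022": 12.89, "1024": 7.36
    }
  },
  "ssc": {
    "intercept": 36.33,
    "terms": {
      "418": -76.42, "425": 84.97, "439": 26.85, "488": -48.79, "505": 30.30,
      "695": -21.61, "705": 77.22, "720": -67.04, "824": -29.14, "883": -31.90,
      "885": 222.32, "888": 61.35, "914": -176.46, "919": -122.60, "940": 72.51,
      "961": 68.45, "990": -134.16, "1019": 81.12
    }
  }
}
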