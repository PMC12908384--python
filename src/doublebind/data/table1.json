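{
  "conditions": {
    "NK": {
      "K_N": 1.0,
      "K_R": 0.779,
      "K_S": 1.27,
      "alpha_RS": 0.0526,
      "alpha_SR": 1.38,
      "fixed": [
        "K_N",
        "K_R",
        "K_S"
      ],
      "lambda_RN": 0.0558,
      "lambda_SN": 0.0308,
      "r_N": 0.0178,
      "r_R": 0.0438,
      "r_S": 0.034
    },
    "RT": {
      "K_N": 1.0,
      "K_R": 0.779,
      "K_S": 1.27,
      "alpha_RS": 0.99,
      "alpha_SR": 2.36,
      "fixed": [
        "K_N",
        "K_R",
        "K_S",
        "lambda_RN",
        "lambda_SN",
        "r_N"
      ],
      "lambda_RN": 0.0,
      "lambda_SN": 0.0,
      "r_N": 0.0,
      "r_R": 0.0218,
      "r_S": 0.0162
    },
    "RTNK": {
      "K_N": 1.0,
      "K_R": 0.779,
      "K_S": 1.27,
      "alpha_RS": 1.83,
      "alpha_SR": 1.96,
      "fixed": [
        "K_N",
        "K_R",
        "K_S"
      ],
      "lambda_RN": 0.0945,
      "lambda_SN": 0.0865,
      "r_N": 0.0245,
      "r_R": 0.0331,
      "r_S": 0.023
    },
    "UT": {
      "K_N": 1.0,
      "K_R": 0.779,
      "K_S": 1.27,
      "alpha_RS": 0.3,
      "alpha_SR": 1.54,
      "fixed": [
        "K_N",
        "lambda_RN",
        "lambda_SN",
        "r_N"
      ],
      "lambda_RN": 0.0,
      "lambda_SN": 0.0,
      "r_N": 0.0,
      "r_R": 0.0357,
      "r_S": 0.032
    }
  },
  "sha256": "a3278a0a427f30d8395ed29cf60c4c73818dd2e8ff8491039149f57649b80673"
}
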