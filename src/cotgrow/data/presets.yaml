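# Fitted relative-logistic growth-model coefficients for cotton.
#
# Exponent convention: relative index = 1 / (1 + exp(intercept + slope*x
# [+ curvature*x^2])) with x the relative cumulative driver on [0, 1].
# Coefficients are stored exactly as published (3-4 significant figures);
# nothing is re-fitted at load time.
#
# all_region: pooled multi-region models, one per growth index and driver.
# regional: per-region coefficient table. For each region/index, "cgdd" holds
#   the thermal-time-driven fit (a, b[, c]); "ceto_fit" the directly fitted
#   evapotranspiration-driven coefficients (d, e[, f]); "ceto_cal" the same
#   coefficients obtained algebraically from the cgdd fit through the linear
#   driver link; "re" the published relative deviation |cal - fit| / |fit|.

all_region:
  H:
    CGDD: {intercept: 2.820, slope: -5.424}
    CETO: {intercept: 3.212, slope: -6.091}
  LAI:
    CGDD: {intercept: 4.553, slope: -16.03, curvature: 10.09}
    CETO: {intercept: 5.024, slope: -15.66, curvature: 9.5}
  D:
    CGDD: {intercept: 2.877, slope: -5.764}
    CETO: {intercept: 3.206, slope: -6.163}

regional:
  H:
    Korla:
      cgdd: {intercept: 3.190, slope: -5.969}
      ceto_fit: {intercept: 3.525, slope: -6.841}
      ceto_cal: {intercept: 3.548, slope: -6.399}
      re: {intercept: 0.0065, slope: 0.0646}
    Akesu:
      cgdd: {intercept: 2.960, slope: -5.376}
      ceto_fit: {intercept: 2.980, slope: -5.184}
      ceto_cal: {intercept: 3.124, slope: -5.418}
      re: {intercept: 0.0485, slope: 0.0451}
    Shihezi:
      cgdd: {intercept: 3.199, slope: -5.425}
      ceto_fit: {intercept: 3.676, slope: -5.296}
      ceto_cal: {intercept: 3.463, slope: -5.705}
      re: {intercept: 0.0578, slope: 0.0773}
    Changji:
      cgdd: {intercept: 2.461, slope: -6.571}
      ceto_fit: {intercept: 2.769, slope: -6.352}
      ceto_cal: {intercept: 2.977, slope: -6.804}
      re: {intercept: 0.0751, slope: 0.0711}
    Urumqi:
      cgdd: {intercept: 3.244, slope: -7.648}
      ceto_fit: {intercept: 4.001, slope: -8.201}
      ceto_cal: {intercept: 3.979, slope: -8.304}
      re: {intercept: 0.0054, slope: 0.0126}
    Total:
      cgdd: {intercept: 2.820, slope: -5.424}
      ceto_fit: {intercept: 3.212, slope: -6.091}
      ceto_cal: {intercept: 3.149, slope: -5.731}
      re: {intercept: 0.0196, slope: 0.0592}
  LAI:
    Korla:
      cgdd: {intercept: 2.266, slope: 0.899, curvature: -10.490}
      ceto_fit: {intercept: 1.985, slope: 2.491, curvature: -12.430}
      ceto_cal: {intercept: 2.174, slope: 2.312, curvature: -11.246}
      re: {intercept: 0.0954, slope: 0.0718, curvature: 0.0953}
    Akesu:
      cgdd: {intercept: 5.415, slope: -19.380, curvature: 12.490}
      ceto_fit: {intercept: 5.502, slope: -19.075, curvature: 12.629}
      ceto_cal: {intercept: 6.020, slope: -20.301, curvature: 12.587}
      re: {intercept: 0.0941, slope: 0.0643, curvature: 0.0033}
    Shihezi:
      cgdd: {intercept: 2.599, slope: -5.198, curvature: -2.850}
      ceto_fit: {intercept: 2.545, slope: -5.928, curvature: -2.685}
      ceto_cal: {intercept: 2.846, slope: -5.174, curvature: -2.997}
      re: {intercept: 0.1181, slope: 0.1272, curvature: 0.1163}
    Changji:
      cgdd: {intercept: 2.274, slope: 5.934, curvature: -38.620}
      ceto_fit: {intercept: 1.798, slope: 10.997, curvature: -35.790}
      ceto_cal: {intercept: 1.570, slope: 12.424, curvature: -39.988}
      re: {intercept: 0.1269, slope: 0.1298, curvature: 0.1173}
    Karamay:
      cgdd: {intercept: 2.844, slope: -10.850, curvature: 4.294}
      ceto_fit: {intercept: 3.122, slope: -10.480, curvature: 4.320}
      ceto_cal: {intercept: 2.979, slope: -9.817, curvature: 3.848}
      re: {intercept: 0.0460, slope: 0.0632, curvature: 0.1093}
    Liaoning:
      cgdd: {intercept: 4.018, slope: -13.660, curvature: 6.960}
      ceto_fit: {intercept: 5.414, slope: -18.220, curvature: 9.050}
      ceto_cal: {intercept: 5.505, slope: -17.038, curvature: 7.854}
      re: {intercept: 0.0167, slope: 0.0649, curvature: 0.1322}
    Hubei:
      cgdd: {intercept: 2.462, slope: -8.495, curvature: 6.180}
      ceto_fit: {intercept: 2.281, slope: -7.467, curvature: 5.350}
      ceto_cal: {intercept: 2.597, slope: -8.436, curvature: 6.000}
      re: {intercept: 0.1381, slope: 0.1298, curvature: 0.1215}
    He'nan:
      cgdd: {intercept: 5.490, slope: -20.690, curvature: 13.830}
      ceto_fit: {intercept: 5.839, slope: -19.850, curvature: 12.361}
      ceto_cal: {intercept: 6.517, slope: -22.240, curvature: 13.968}
      re: {intercept: 0.1161, slope: 0.1204, curvature: 0.1300}
    Hebei:
      cgdd: {intercept: 7.650, slope: -28.670, curvature: 20.850}
      ceto_fit: {intercept: 13.511, slope: -40.650, curvature: 21.870}
      ceto_cal: {intercept: 15.910, slope: -47.635, curvature: 25.551}
      re: {intercept: 0.1776, slope: 0.1718, curvature: 0.1683}
    Total:
      cgdd: {intercept: 4.553, slope: -16.03, curvature: 10.09}
      ceto_fit: {intercept: 5.024, slope: -15.66, curvature: 9.500}
      ceto_cal: {intercept: 5.563, slope: -18.230, curvature: 11.263}
      re: {intercept: 0.1072, slope: 0.1641, curvature: 0.1856}
  D:
    Korla:
      cgdd: {intercept: 4.452, slope: -7.963}
      ceto_fit: {intercept: 5.319, slope: -9.103}
      ceto_cal: {intercept: 4.930, slope: -8.537}
      re: {intercept: 0.0732, slope: 0.0622}
    Akesu:
      cgdd: {intercept: 2.673, slope: -5.846}
      ceto_fit: {intercept: 2.983, slope: -5.655}
      ceto_cal: {intercept: 2.852, slope: -5.891}
      re: {intercept: 0.0440, slope: 0.0418}
    Shihezi:
      cgdd: {intercept: 2.557, slope: -5.557}
      ceto_fit: {intercept: 2.990, slope: -6.246}
      ceto_cal: {intercept: 2.828, slope: -5.844}
      re: {intercept: 0.0542, slope: 0.0644}
    Liaoning:
      cgdd: {intercept: 2.352, slope: -6.638}
      ceto_fit: {intercept: 3.250, slope: -8.025}
      ceto_cal: {intercept: 3.038, slope: -7.490}
      re: {intercept: 0.0651, slope: 0.0666}
    Hubei:
      cgdd: {intercept: 4.693, slope: -9.715}
      ceto_fit: {intercept: 4.771, slope: -9.564}
      ceto_cal: {intercept: 4.846, slope: -9.432}
      re: {intercept: 0.0157, slope: 0.0138}
    He'nan:
      cgdd: {intercept: 5.942, slope: -10.400}
      ceto_fit: {intercept: 5.978, slope: -9.726}
      ceto_cal: {intercept: 6.442, slope: -10.504}
      re: {intercept: 0.0776, slope: 0.0800}
    Total:
      cgdd: {intercept: 2.877, slope: -5.764}
      ceto_fit: {intercept: 3.206, slope: -6.163}
      ceto_cal: {intercept: 3.227, slope: -6.090}
      re: {intercept: 0.0065, slope: 0.0119}
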