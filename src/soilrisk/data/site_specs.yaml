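# Per-land-use concentration statistics (mg/kg dry weight) for the six
# monitored potentially toxic elements in the Jashore district urban-soil
# survey: sample count, mean, sample SD and observed range per element.
# These are the generator targets for the synthetic study table and the
# site means the index chain is validated against.
sites:
  PA:
    n: 3
    As: {mean: 8.56, sd: 4.32, lower: 3.32, upper: 13.90}
    Cd: {mean: 0.85, sd: 0.18, lower: 0.70, upper: 1.05}
    Pb: {mean: 6.78, sd: 6.48, lower: 1.16, upper: 13.87}
    Cr: {mean: 38.85, sd: 18.27, lower: 20.09, upper: 56.58}
    Ni: {mean: 12.99, sd: 6.23, lower: 5.98, upper: 17.88}
    Cu: {mean: 15.64, sd: 7.03, lower: 9.13, upper: 23.10}
  PG:
    n: 8
    As: {mean: 7.91, sd: 3.61, lower: 2.13, upper: 13.86}
    Cd: {mean: 0.78, sd: 0.40, lower: 0.10, upper: 1.20}
    Pb: {mean: 8.60, sd: 4.19, lower: 2.74, upper: 15.34}
    Cr: {mean: 30.44, sd: 9.70, lower: 18.03, upper: 43.01}
    Ni: {mean: 15.72, sd: 6.31, lower: 5.32, upper: 23.10}
    Cu: {mean: 16.79, sd: 6.18, lower: 5.58, upper: 28.35}
  M:
    n: 8
    As: {mean: 5.15, sd: 2.31, lower: 1.80, upper: 8.88}
    Cd: {mean: 0.98, sd: 0.45, lower: 0.30, upper: 1.80}
    Pb: {mean: 24.50, sd: 10.44, lower: 11.37, upper: 38.93}
    Cr: {mean: 48.75, sd: 16.52, lower: 17.09, upper: 72.09}
    Ni: {mean: 9.29, sd: 4.18, lower: 2.19, upper: 14.23}
    Cu: {mean: 32.14, sd: 9.61, lower: 11.91, upper: 43.14}
  BF:
    n: 8
    As: {mean: 10.16, sd: 3.27, lower: 4.60, upper: 14.50}
    Cd: {mean: 1.09, sd: 0.61, lower: 0.23, upper: 2.10}
    Pb: {mean: 28.87, sd: 10.65, lower: 13.79, upper: 45.76}
    Cr: {mean: 40.24, sd: 14.52, lower: 12.01, upper: 59.09}
    Ni: {mean: 20.68, sd: 7.54, lower: 7.18, upper: 29.11}
    Cu: {mean: 33.48, sd: 8.70, lower: 14.51, upper: 44.10}
  IA:
    n: 4
    As: {mean: 6.69, sd: 3.01, lower: 3.76, upper: 11.54}
    Cd: {mean: 1.21, sd: 0.58, lower: 0.70, upper: 2.03}
    Pb: {mean: 78.36, sd: 35.04, lower: 34.58, upper: 113.26}
    Cr: {mean: 29.51, sd: 7.39, lower: 21.04, upper: 37.09}
    Ni: {mean: 16.50, sd: 5.78, lower: 8.10, upper: 21.30}
    Cu: {mean: 19.25, sd: 3.98, lower: 15.10, upper: 24.30}
  PP:
    n: 8
    As: {mean: 6.81, sd: 2.75, lower: 2.45, upper: 11.21}
    Cd: {mean: 0.94, sd: 0.31, lower: 0.30, upper: 1.23}
    Pb: {mean: 15.48, sd: 9.44, lower: 5.66, upper: 28.70}
    Cr: {mean: 33.69, sd: 10.58, lower: 19.77, upper: 50.08}
    Ni: {mean: 10.05, sd: 5.28, lower: 2.10, upper: 18.88}
    Cu: {mean: 28.47, sd: 14.03, lower: 10.24, upper: 52.15}
  MW:
    n: 8
    As: {mean: 11.39, sd: 4.23, lower: 5.99, upper: 18.09}
    Cd: {mean: 2.05, sd: 0.84, lower: 1.02, upper: 3.58}
    Pb: {mean: 64.36, sd: 27.69, lower: 33.10, upper: 102.78}
    Cr: {mean: 33.45, sd: 14.62, lower: 15.02, upper: 55.12}
    Ni: {mean: 51.52, sd: 12.03, lower: 29.89, upper: 68.23}
    Cu: {mean: 124.67, sd: 48.49, lower: 65.97, upper: 212.57}
  BS:
    n: 3
    As: {mean: 6.96, sd: 4.40, lower: 2.13, upper: 12.78}
    Cd: {mean: 1.25, sd: 0.86, lower: 0.40, upper: 2.11}
    Pb: {mean: 27.90, sd: 15.02, lower: 13.68, upper: 43.60}
    Cr: {mean: 41.15, sd: 19.11, lower: 24.55, upper: 62.04}
    Ni: {mean: 14.27, sd: 4.41, lower: 9.19, upper: 17.13}
    Cu: {mean: 42.04, sd: 24.38, lower: 21.82, upper: 69.12}
  PS:
    n: 8
    As: {mean: 7.77, sd: 3.90, lower: 2.56, upper: 14.69}
    Cd: {mean: 0.94, sd: 0.64, lower: 0.10, upper: 1.87}
    Pb: {mean: 9.49, sd: 6.29, lower: 2.07, upper: 19.06}
    Cr: {mean: 37.88, sd: 12.96, lower: 13.99, upper: 58.09}
    Ni: {mean: 17.09, sd: 6.98, lower: 3.19, upper: 25.87}
    Cu: {mean: 26.18, sd: 11.52, lower: 4.23, upper: 42.11}
  RA:
    n: 8
    As: {mean: 5.67, sd: 2.72, lower: 1.90, upper: 10.70}
    Cd: {mean: 0.60, sd: 0.35, lower: 0.10, upper: 1.03}
    Pb: {mean: 4.09, sd: 4.30, lower: 0.40, upper: 12.09}
    Cr: {mean: 5.87, sd: 4.73, lower: 0.90, upper: 12.09}
    Ni: {mean: 10.17, sd: 5.00, lower: 2.98, upper: 18.23}
    Cu: {mean: 12.53, sd: 7.89, lower: 3.82, upper: 28.30}
  WDA:
    n: 5
    As: {mean: 6.27, sd: 2.49, lower: 3.66, upper: 10.87}
    Cd: {mean: 1.24, sd: 0.56, lower: 0.69, upper: 2.01}
    Pb: {mean: 29.75, sd: 11.20, lower: 12.09, upper: 41.01}
    Cr: {mean: 38.54, sd: 13.47, lower: 18.03, upper: 55.08}
    Ni: {mean: 19.00, sd: 8.14, lower: 11.94, upper: 32.12}
    Cu: {mean: 32.88, sd: 10.87, lower: 22.89, upper: 51.32}
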