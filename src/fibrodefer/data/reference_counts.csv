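table,printed,numerator,denominator,consistent
2,0.79,74,94,1
2,0.65,20,31,1
2,0.96,24,25,1
2,0.95,89,94,1
2,0.84,26,31,1
2,0.92,23,25,1
2,0.20,1,5,1
2,0.53,10,19,1
2,0.00,0,1,1
2,0.20,1,5,1
2,0.74,14,19,1
2,0.00,0,1,1
2,0.85,66,78,1
2,0.71,10,14,1
2,0.77,17,22,1
2,0.87,68,78,1
2,0.79,11,14,1
2,0.82,18,22,1
2,0.62,13,21,1
2,0.75,27,36,1
2,0.25,1,4,1
2,0.62,13,21,1
2,0.81,29,36,1
2,0.5,2,4,1
2,0.83,43,52,1
2,1.00,5,5,1
2,0.75,15,20,1
2,0.88,46,52,1
2,1.0,5,5,1
2,0.75,15,20,1
2,0.68,32,47,1
2,0.80,36,45,1
2,0.33,2,6,1
2,0.68,32,47,1
2,0.82,37,45,1
2,0.5,3,6,1
3,0.67,68,101,1
3,0.90,82,91,1
3,0.66,52,79,1
3,0.93,105,113,1
3,0.66,42,64,1
3,0.93,119,128,1
3,0.69,70,101,1
3,0.93,85,91,1
3,0.65,51,79,1
3,0.92,104,113,1
3,0.67,43,64,1
3,0.89,114,128,1
3,0.72,73,101,1
3,0.90,82,91,1
3,0.51,40,79,1
3,0.93,105,113,1
3,0.52,33,64,1
3,0.94,120,128,1
3,0.69,70,101,1
3,0.93,85,91,1
3,0.67,53,79,1
3,0.94,106,113,1
3,0.69,44,64,1
3,0.93,119,128,1
3,0.76,77,101,1
3,0.91,83,91,1
3,0.70,55,79,1
3,0.93,105,113,1
3,0.69,44,64,1
3,0.93,119,128,1
3,0.67,68,101,1
3,0.81,74,91,1
3,0.65,51,79,1
3,0.81,91,113,1
3,0.66,42,64,1
3,0.78,100,128,1
3,0.34,34,101,1
3,0.90,82,91,1
3,0.14,11,79,1
3,0.93,105,113,1
3,0.06,4,64,1
3,0.93,119,128,1
3,0.71,72,101,1
3,0.74,67,91,1
3,0.66,52,79,1
3,0.75,85,113,1
3,0.66,42,64,1
3,0.73,94,128,1
3,0.49,49,101,1
3,0.90,82,91,1
3,0.24,19,79,1
3,0.94,106,113,1
3,0.16,10,64,1
3,0.95,121,128,1
3,0.95,89,94,1
3,0.60,3,5,1
3,0.88,69,78,1
3,0.86,18,21,1
3,0.92,48,52,1
3,0.66,31,47,1
3,0.97,91,94,1
3,0.20,1,5,1
3,0.87,68,78,1
3,0.67,14,21,1
3,0.92,48,52,1
3,0.55,26,47,1
3,0.81,76,94,1
3,0.60,3,5,1
3,0.77,60,78,1
3,0.86,18,21,1
3,0.88,46,52,1
3,0.68,32,47,1
3,0.95,89,94,1
3,0.60,3,5,1
3,0.88,69,78,1
3,0.86,18,21,1
3,0.92,48,52,1
3,0.66,31,47,1
3,0.96,90,94,1
3,0.60,3,5,1
3,0.88,69,78,1
3,0.86,18,21,1
3,0.96,50,52,1
3,0.66,31,47,1
3,1.00,94,94,1
3,0.00,0,5,1
3,0.87,68,78,1
3,0.14,3,21,1
3,0.92,48,52,1
3,0.06,3,47,1
3,0.51,48,94,1
3,0.60,3,5,1
3,0.23,18,78,1
3,0.86,18,21,1
3,0.46,24,52,1
3,0.66,31,47,1
3,0.94,88,94,1
3,0.40,2,5,1
3,0.88,69,78,1
3,0.38,8,21,1
3,0.92,48,52,1
3,0.19,9,47,1
3,0.41,39,94,1
3,0.60,3,5,1
3,0.45,35,78,1
3,0.86,18,21,1
3,0.46,24,52,1
3,0.70,33,47,1
3,0.84,26,31,1
3,0.68,13,19,1
3,0.79,11,14,1
3,0.81,29,36,1
3,1.00,5,5,1
3,0.76,34,45,1
3,0.84,26,31,1
3,0.68,13,19,1
3,0.79,11,14,1
3,0.86,31,36,1
3,1.00,5,5,1
3,0.89,40,45,1
3,0.84,26,31,1
3,0.68,13,19,1
3,0.79,11,14,1
3,0.86,31,36,1
3,1.00,5,5,1
3,0.89,40,45,1
3,0.84,26,31,1
3,0.74,14,19,1
3,0.79,11,14,1
3,0.92,33,36,1
3,1.00,5,5,1
3,0.89,40,45,1
3,0.90,28,31,1
3,0.68,13,19,1
3,0.86,12,14,1
3,0.81,29,36,1
3,1.00,5,5,1
3,0.89,40,45,1
3,0.83,20,24,1
3,0.69,9,13,1
3,0.80,8,10,1
3,0.52,14,27,1
3,1.00,4,4,1
3,0.49,16,33,0
3,0.83,20,24,1
3,0.69,9,13,1
3,0.3,3,10,1
3,0.85,23,27,1
3,0.25,1,4,1
3,0.82,27,33,1
3,0.83,20,24,1
3,0.31,4,13,1
3,0.80,8,10,1
3,0.44,12,27,1
3,1.00,4,4,1
3,0.46,15,33,0
3,0.38,9,24,1
3,0.69,9,13,1
3,0.50,5,10,1
3,0.78,21,27,1
3,0.50,2,4,1
3,0.73,24,33,1
4,0.78,110,141,1
4,0.62,34,55,1
4,0.84,101,120,1
4,0.89,68,76,1
4,0.70,71,101,1
4,0.87,83,95,1
4,0.79,111,141,1
4,0.73,40,55,1
4,0.83,100,120,1
4,0.74,56,76,1
4,0.70,71,101,1
4,0.80,76,95,1
4,0.84,119,141,1
4,0.64,35,55,1
4,0.56,67,120,1
4,0.91,69,76,1
4,0.48,48,101,1
4,0.87,83,95,1
4,0.78,110,141,1
4,0.64,35,55,1
4,0.85,102,120,1
4,0.91,69,76,1
4,0.71,72,101,1
4,0.88,84,95,1
4,0.82,115,141,1
4,0.62,34,55,1
4,0.88,106,120,1
4,0.89,68,76,1
4,0.75,76,101,1
4,0.87,83,95,1
4,0.80,113,141,1
4,0.84,46,55,1
4,0.83,100,120,1
4,0.71,54,76,1
4,0.71,72,101,1
4,0.73,69,95,1
4,0.91,128,141,1
4,0.60,33,55,1
4,0.35,42,120,1
4,0.91,69,76,1
4,0.38,38,101,1
4,0.87,83,95,1
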