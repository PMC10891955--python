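,bio1,bio2,bio3,bio4,bio5,bio6,bio7,bio8,bio9,bio10,bio11,bio12,bio13,bio14,bio15,bio16,bio17,bio18,bio19,bio20
bio1,1.00,0.03,0.72,-0.71,0.05,0.63,-0.36,-0.56,0.88,-0.14,0.88,0.24,0.39,0.01,0.29,0.43,0.02,-0.66,0.64,0.26
bio2,0.03,1.00,-0.56,0.60,0.99,-0.73,0.91,-0.12,-0.19,0.92,-0.38,-0.85,-0.63,-0.65,0.89,-0.69,-0.69,-0.60,-0.61,0.92
bio3,0.72,-0.56,1.00,-0.98,-0.60,0.95,-0.85,-0.47,0.86,-0.77,0.95,0.77,0.80,0.27,-0.18,0.86,0.32,-0.28,0.96,-0.40
bio4,-0.71,0.60,-0.98,1.00,0.62,-0.98,0.88,0.53,-0.88,0.79,-0.96,-0.75,-0.76,-0.22,0.23,-0.81,-0.28,0.26,-0.94,0.38
bio5,0.05,0.99,-0.60,0.62,1.00,-0.73,0.91,-0.07,-0.22,0.95,-0.39,-0.87,-0.67,-0.58,0.83,-0.73,-0.64,-0.54,-0.64,0.93
bio6,0.63,-0.73,0.95,-0.98,-0.73,1.00,-0.95,-0.38,0.79,-0.84,0.91,0.82,0.78,0.39,-0.43,0.83,0.44,-0.07,0.93,-0.51
bio7,-0.36,0.91,-0.85,0.88,0.91,-0.95,1.00,0.20,-0.58,0.96,-0.73,-0.91,-0.79,-0.51,0.65,-0.84,-0.56,-0.21,-0.86,0.75
bio8,-0.56,-0.12,-0.47,0.53,-0.07,-0.38,0.20,1.00,-0.81,0.20,-0.59,0.12,0.02,0.68,-0.48,0.00,0.64,0.68,-0.28,-0.39
bio9,0.88,-0.19,0.86,-0.88,-0.22,0.79,-0.58,-0.81,1.00,-0.46,0.95,0.36,0.46,-0.16,0.20,0.50,-0.12,-0.61,0.74,0.07
bio10,-0.14,0.92,-0.77,0.79,0.95,-0.84,0.96,0.20,-0.46,1.00,-0.59,-0.87,-0.74,-0.39,0.64,-0.79,-0.46,-0.27,-0.77,0.81
bio11,0.88,-0.38,0.95,-0.96,-0.39,0.91,-0.73,-0.59,0.95,-0.59,1.00,0.60,0.68,0.13,-0.02,0.72,0.17,-0.46,0.89,-0.14
bio12,0.24,-0.85,0.77,-0.75,-0.87,0.82,-0.91,0.12,0.36,-0.87,0.60,1.00,0.94,0.68,-0.67,0.96,0.72,0.25,0.88,-0.83
bio13,0.39,-0.63,0.80,-0.76,-0.67,0.78,-0.79,0.02,0.46,-0.74,0.68,0.94,1.00,0.53,-0.41,0.98,0.57,-0.05,0.93,-0.62
bio14,0.01,-0.65,0.27,-0.22,-0.58,0.39,-0.51,0.68,-0.16,-0.39,0.13,0.68,0.53,1.00,-0.77,0.59,1.00,0.63,0.40,-0.74
bio15,0.29,0.89,-0.18,0.23,0.83,-0.43,0.65,-0.48,0.20,0.64,-0.02,-0.67,-0.41,-0.77,1.00,-0.44,-0.80,-0.85,-0.28,0.87
bio16,0.43,-0.69,0.86,-0.81,-0.73,0.83,-0.84,0.00,0.50,-0.79,0.72,0.96,0.98,0.59,-0.44,1.00,0.63,0.00,0.95,-0.67
bio17,0.02,-0.69,0.32,-0.28,-0.64,0.44,-0.56,0.64,-0.12,-0.46,0.17,0.72,0.57,1.00,-0.80,0.63,1.00,0.63,0.44,-0.77
bio18,-0.66,-0.60,-0.28,0.26,-0.54,-0.07,-0.21,0.68,-0.61,-0.27,-0.46,0.25,-0.05,0.63,-0.85,0.00,0.63,1.00,-0.22,-0.70
bio19,0.64,-0.61,0.96,-0.94,-0.64,0.93,-0.86,-0.28,0.74,-0.77,0.89,0.88,0.93,0.40,-0.28,0.95,0.44,-0.22,1.00,-0.49
bio20,0.26,0.92,-0.40,0.38,0.93,-0.51,0.75,-0.39,0.07,0.81,-0.14,-0.83,-0.62,-0.74,0.87,-0.67,-0.77,-0.70,-0.49,1.00
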