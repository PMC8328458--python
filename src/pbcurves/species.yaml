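# Five virtual-species coefficient sets (logistic occurrence models).
# form: linear    -> logit P = b0 + b1*x1 + b2*x2 + b3*x3
# form: quadratic -> logit P = b0 + b1*(x1-mean1)^2 + b2*(x2-mean2)^2 + b3*(x3-mean3)^2
# covariate_means omitted -> means of the supplied environmental field.
spec1: {b0: -10,  b1: -0.15, b2: -2.5, b3: 28,  form: linear}
spec2: {b0: 0.5,  b1: -1.5,  b2: -8.5, b3: 18,  form: linear}
spec3: {b0: -0.4, b1: -0.8,  b2: -5,   b3: 18,  form: linear}
spec4: {b0: -5,   b1: -0.2,  b2: 5,    b3: 30,  form: quadratic}
spec5: {b0: 2.8,  b1: 5,     b2: -5,   b3: -50, form: quadratic}
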