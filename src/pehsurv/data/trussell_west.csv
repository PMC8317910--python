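# Trussell multiplier coefficients, West family, children-dead variant.
# Reference constants for converting the proportion dead D(i) among children
# of women in 5-year age group i into q(x(i)) via
#   k(i) = a(i) + b(i)*(P1/P2) + c(i)*(P2/P3).
# Standard correspondence: i=1..7 -> x = 1,2,3,5,10,15,20.
# Verify against the printed reference tables before production use; the
# test-suite exercises the arithmetic with synthetic coefficients so code
# correctness does not depend on this transcription.
i,age_x,a,b,c
1,1,1.1415,-2.7070,0.7663
2,2,1.2563,-0.5381,-0.2637
3,3,1.1851,0.0633,-0.4177
4,5,1.1720,0.2341,-0.4272
5,10,1.1865,0.3080,-0.4452
6,15,1.1746,0.3314,-0.4537
7,20,1.1639,0.3190,-0.4435
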