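algorithm,f1,f2,f3,f4,f5,f6,f7,f8,f9,f10,f11,f12
SPSO,0.00E+00,1.54E+00,3.55E-04,1.98E+00,3.56E+01,7.67E-01,3.38E-03,-7.28E+03,3.48E+01,1.04E+00,6.56E-03,2.42E-02
APSO,2.47E-37,3.02E-20,5.88E+00,6.62E-01,2.94E+01,6.67E-02,1.17E-02,-2.10E+04,5.00E+01,3.15E-01,1.42E-02,1.63E-01
GPSO,2.83E-23,6.15E-10,2.15E+01,1.20E+00,3.92E+01,6.67E-02,1.27E-02,-1.30E+04,3.30E+01,8.41E-13,1.05E-02,3.11E-02
FA,1.22E-03,4.80E-02,3.67E+01,4.38E-02,8.28E+01,0.00E+00,3.50E-02,-7.04E+03,3.49E+01,8.82E-03,2.95E-03,5.87E-06
AdaFa-S1,1.56E-55,3.45E-28,1.93E-54,1.60E-28,2.87E+01,0.00E+00,3.00E-05,-4.83E+03,5.55E+00,4.56E-15,0.00E+00,8.80E-02
AdaFa-S2,2.36E-87,5.09E-45,4.19E-86,6.85E-45,2.87E+01,0.00E+00,3.61E-05,-4.87E+03,7.20E+00,8.47E-15,2.96E-17,9.33E-02
AdaFa-S3,1.26E-123,7.44E-63,2.16E-122,1.30E-62,2.88E+01,0.00E+00,2.20E-05,-4.96E+03,3.23E+00,2.78E-14,9.25E-16,6.91E-03
AdaFa-S4,3.51E-78,8.13E-40,8.95E-77,1.11E-39,2.87E+01,0.00E+00,4.59E-05,-4.90E+03,3.03E-14,6.10E-15,3.33E-17,1.73E-02
AdaFa-S5,3.67E-74,4.75E-38,2.47E-73,7.16E-38,2.88E+01,0.00E+00,3.55E-05,-4.94E+03,4.21E+00,1.14E-14,2.22E-17,3.80E-02
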