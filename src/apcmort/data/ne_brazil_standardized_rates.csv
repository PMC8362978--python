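# Published directly standardized female breast-cancer mortality rates
# (deaths per 100,000 women, Segi world standard) for north-east Brazil and
# its nine states, quinquennia 1980-1984 ... 2015-2019.
# measure: UMR = uncorrected; CMR = corrected for ill-defined causes and
# incomplete cancer diagnoses; CMRQIUD = fully corrected (ill-defined,
# incomplete diagnosis and death under-registration).
locality,measure,period_start,rate
Northeast,UMR,1980,7.16
Northeast,UMR,1985,7.86
Northeast,UMR,1990,8.69
Northeast,UMR,1995,9.68
Northeast,UMR,2000,11.33
Northeast,UMR,2005,14.95
Northeast,UMR,2010,16.87
Northeast,UMR,2015,18.76
Northeast,CMR,1980,10.58
Northeast,CMR,1985,11.47
Northeast,CMR,1990,12.25
Northeast,CMR,1995,13.05
Northeast,CMR,2000,14.55
Northeast,CMR,2005,17.16
Northeast,CMR,2010,18.91
Northeast,CMR,2015,19.70
Northeast,CMRQIUD,1980,14.70
Northeast,CMRQIUD,1985,15.95
Northeast,CMRQIUD,1990,15.92
Northeast,CMRQIUD,1995,16.97
Northeast,CMRQIUD,2000,18.63
Northeast,CMRQIUD,2005,21.96
Northeast,CMRQIUD,2010,24.20
Northeast,CMRQIUD,2015,25.22
Alagoas,UMR,1980,7.95
Alagoas,UMR,1985,7.23
Alagoas,UMR,1990,7.71
Alagoas,UMR,1995,7.15
Alagoas,UMR,2000,8.99
Alagoas,UMR,2005,13.71
Alagoas,UMR,2010,15.88
Alagoas,UMR,2015,16.10
Alagoas,CMR,1980,12.07
Alagoas,CMR,1985,10.79
Alagoas,CMR,1990,11.15
Alagoas,CMR,1995,10.28
Alagoas,CMR,2000,11.98
Alagoas,CMR,2005,15.96
Alagoas,CMR,2010,18.00
Alagoas,CMR,2015,17.50
Alagoas,CMRQIUD,1980,12.31
Alagoas,CMRQIUD,1985,11.03
Alagoas,CMRQIUD,1990,11.56
Alagoas,CMRQIUD,1995,10.67
Alagoas,CMRQIUD,2000,13.70
Alagoas,CMRQIUD,2005,18.20
Alagoas,CMRQIUD,2010,20.53
Alagoas,CMRQIUD,2015,19.95
Bahia,UMR,1980,7.77
Bahia,UMR,1985,8.76
Bahia,UMR,1990,8.97
Bahia,UMR,1995,9.41
Bahia,UMR,2000,10.50
Bahia,UMR,2005,13.12
Bahia,UMR,2010,16.08
Bahia,UMR,2015,17.60
Bahia,CMR,1980,10.76
Bahia,CMR,1985,11.70
Bahia,CMR,1990,11.75
Bahia,CMR,1995,12.23
Bahia,CMR,2000,13.36
Bahia,CMR,2005,15.57
Bahia,CMR,2010,18.63
Bahia,CMR,2015,20.16
Bahia,CMRQIUD,1980,11.85
Bahia,CMRQIUD,1985,12.87
Bahia,CMRQIUD,1990,13.52
Bahia,CMRQIUD,1995,14.05
Bahia,CMRQIUD,2000,15.50
Bahia,CMRQIUD,2005,18.06
Bahia,CMRQIUD,2010,21.62
Bahia,CMRQIUD,2015,23.39
Ceara,UMR,1980,7.41
Ceara,UMR,1985,7.92
Ceara,UMR,1990,8.55
Ceara,UMR,1995,11.51
Ceara,UMR,2000,13.99
Ceara,UMR,2005,17.05
Ceara,UMR,2010,18.30
Ceara,UMR,2015,21.82
Ceara,CMR,1980,10.45
Ceara,CMR,1985,11.58
Ceara,CMR,1990,12.50
Ceara,CMR,1995,15.11
Ceara,CMR,2000,18.14
Ceara,CMR,2005,19.62
Ceara,CMR,2010,20.33
Ceara,CMR,2015,23.61
Ceara,CMRQIUD,1980,13.60
Ceara,CMRQIUD,1985,15.06
Ceara,CMRQIUD,1990,14.86
Ceara,CMRQIUD,1995,17.98
Ceara,CMRQIUD,2000,20.68
Ceara,CMRQIUD,2005,22.38
Ceara,CMRQIUD,2010,23.17
Ceara,CMRQIUD,2015,26.92
Maranhao,UMR,1980,2.34
Maranhao,UMR,1985,3.14
Maranhao,UMR,1990,3.53
Maranhao,UMR,1995,3.91
Maranhao,UMR,2000,4.33
Maranhao,UMR,2005,8.38
Maranhao,UMR,2010,10.89
Maranhao,UMR,2015,12.11
Maranhao,CMR,1980,3.39
Maranhao,CMR,1985,4.91
Maranhao,CMR,1990,5.51
Maranhao,CMR,1995,5.66
Maranhao,CMR,2000,6.09
Maranhao,CMR,2005,9.35
Maranhao,CMR,2010,11.89
Maranhao,CMR,2015,13.20
Maranhao,CMRQIUD,1980,6.39
Maranhao,CMRQIUD,1985,9.28
Maranhao,CMRQIUD,1990,8.39
Maranhao,CMRQIUD,1995,8.60
Maranhao,CMRQIUD,2000,9.50
Maranhao,CMRQIUD,2005,14.59
Maranhao,CMRQIUD,2010,18.55
Maranhao,CMRQIUD,2015,20.59
Paraiba,UMR,1980,5.40
Paraiba,UMR,1985,5.25
Paraiba,UMR,1990,6.59
Paraiba,UMR,1995,6.07
Paraiba,UMR,2000,8.51
Paraiba,UMR,2005,15.16
Paraiba,UMR,2010,15.66
Paraiba,UMR,2015,16.84
Paraiba,CMR,1980,10.79
Paraiba,CMR,1985,9.69
Paraiba,CMR,1990,11.26
Paraiba,CMR,1995,10.04
Paraiba,CMR,2000,12.25
Paraiba,CMR,2005,17.58
Paraiba,CMR,2010,17.65
Paraiba,CMR,2015,18.25
Paraiba,CMRQIUD,1980,11.22
Paraiba,CMRQIUD,1985,10.08
Paraiba,CMRQIUD,1990,11.98
Paraiba,CMRQIUD,1995,10.69
Paraiba,CMRQIUD,2000,13.70
Paraiba,CMRQIUD,2005,19.70
Paraiba,CMRQIUD,2010,19.74
Paraiba,CMRQIUD,2015,20.92
Pernambuco,UMR,1980,10.01
Pernambuco,UMR,1985,10.94
Pernambuco,UMR,1990,12.77
Pernambuco,UMR,1995,15.16
Pernambuco,UMR,2000,16.40
Pernambuco,UMR,2005,19.68
Pernambuco,UMR,2010,20.19
Pernambuco,UMR,2015,22.19
Pernambuco,CMR,1980,14.73
Pernambuco,CMR,1985,15.87
Pernambuco,CMR,1990,17.54
Pernambuco,CMR,1995,18.75
Pernambuco,CMR,2000,19.72
Pernambuco,CMR,2005,22.01
Pernambuco,CMR,2010,22.24
Pernambuco,CMR,2015,23.96
Pernambuco,CMRQIUD,1980,14.76
Pernambuco,CMRQIUD,1985,15.88
Pernambuco,CMRQIUD,1990,17.90
Pernambuco,CMRQIUD,1995,19.13
Pernambuco,CMRQIUD,2000,20.70
Pernambuco,CMRQIUD,2005,23.09
Pernambuco,CMRQIUD,2010,23.36
Pernambuco,CMRQIUD,2015,25.16
Piaui,UMR,1980,5.42
Piaui,UMR,1985,3.78
Piaui,UMR,1990,5.09
Piaui,UMR,1995,4.84
Piaui,UMR,2000,8.62
Piaui,UMR,2005,13.32
Piaui,UMR,2010,15.93
Piaui,UMR,2015,17.80
Piaui,CMR,1980,7.75
Piaui,CMR,1985,5.86
Piaui,CMR,1990,7.18
Piaui,CMR,1995,6.34
Piaui,CMR,2000,10.94
Piaui,CMR,2005,14.73
Piaui,CMR,2010,17.25
Piaui,CMR,2015,18.75
Piaui,CMRQIUD,1980,13.84
Piaui,CMRQIUD,1985,10.38
Piaui,CMRQIUD,1990,8.53
Piaui,CMRQIUD,1995,7.51
Piaui,CMRQIUD,2000,12.71
Piaui,CMRQIUD,2005,17.09
Piaui,CMRQIUD,2010,19.99
Piaui,CMRQIUD,2015,22.15
Rio Grande do Norte,UMR,1980,5.74
Rio Grande do Norte,UMR,1985,9.52
Rio Grande do Norte,UMR,1990,10.63
Rio Grande do Norte,UMR,1995,10.97
Rio Grande do Norte,UMR,2000,11.51
Rio Grande do Norte,UMR,2005,15.05
Rio Grande do Norte,UMR,2010,17.53
Rio Grande do Norte,UMR,2015,20.07
Rio Grande do Norte,CMR,1980,8.03
Rio Grande do Norte,CMR,1985,13.18
Rio Grande do Norte,CMR,1990,14.35
Rio Grande do Norte,CMR,1995,14.52
Rio Grande do Norte,CMR,2000,14.57
Rio Grande do Norte,CMR,2005,17.24
Rio Grande do Norte,CMR,2010,19.75
Rio Grande do Norte,CMR,2015,22.09
Rio Grande do Norte,CMRQIUD,1980,8.68
Rio Grande do Norte,CMRQIUD,1985,14.41
Rio Grande do Norte,CMRQIUD,1990,16.11
Rio Grande do Norte,CMRQIUD,1995,16.23
Rio Grande do Norte,CMRQIUD,2000,16.89
Rio Grande do Norte,CMRQIUD,2005,20.00
Rio Grande do Norte,CMRQIUD,2010,22.88
Rio Grande do Norte,CMRQIUD,2015,25.63
Sergipe,UMR,1980,7.80
Sergipe,UMR,1985,8.55
Sergipe,UMR,1990,9.48
Sergipe,UMR,1995,9.64
Sergipe,UMR,2000,13.49
Sergipe,UMR,2005,17.44
Sergipe,UMR,2010,20.94
Sergipe,UMR,2015,22.25
Sergipe,CMR,1980,12.24
Sergipe,CMR,1985,13.61
Sergipe,CMR,1990,14.16
Sergipe,CMR,1995,13.63
Sergipe,CMR,2000,16.62
Sergipe,CMR,2005,19.17
Sergipe,CMR,2010,22.58
Sergipe,CMR,2015,23.99
Sergipe,CMRQIUD,1980,12.58
Sergipe,CMRQIUD,1985,13.84
Sergipe,CMRQIUD,1990,14.94
Sergipe,CMRQIUD,1995,14.50
Sergipe,CMRQIUD,2000,18.25
Sergipe,CMRQIUD,2005,21.08
Sergipe,CMRQIUD,2010,24.87
Sergipe,CMRQIUD,2015,26.38
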