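id,reference,iphone_detected,iphone_est,lca_tls_detected,lca_tls_est,riegl_detected,riegl_est,stonex_detected,stonex_est
ID01,11.10,yes,10.30,yes,11.40,yes,11.50,yes,11.90
ID02,16.00,yes,16.70,yes,16.80,yes,16.50,yes,16.80
ID03,16.00,yes,16.90,yes,16.40,yes,16.80,yes,16.70
ID04,16.00,yes,16.30,yes,16.80,yes,16.40,yes,16.90
ID05,16.00,yes,16.20,yes,16.30,yes,16.70,yes,17.00
ID06,16.00,yes,16.70,yes,16.50,yes,16.80,yes,16.90
ID07,16.00,yes,16.80,yes,16.60,yes,16.75,yes,16.80
ID08,25.30,yes,27.40,yes,26.40,yes,25.80,yes,26.20
ID09,25.30,yes,28.30,yes,26.60,yes,26.00,yes,26.40
ID10,50.50,yes,54.31,yes,52.70,yes,51.10,yes,53.10
ID11,2.60,no,,yes,4.80,yes,3.15,yes,5.20
ID12,2.60,no,,yes,4.40,yes,3.08,yes,4.90
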