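id,reference,iphone_detected,iphone_est,lca_tls_detected,lca_tls_est,riegl_detected,riegl_est,stonex_detected,stonex_est
ID01,145.00,yes,152.00,yes,149.00,yes,148.00,yes,151.00
ID02,100.00,yes,102.00,yes,105.00,yes,101.00,yes,108.00
ID03,100.00,yes,108.00,yes,104.00,yes,100.80,yes,102.00
ID04,100.00,yes,105.00,yes,100.80,yes,102.00,yes,102.00
ID05,100.00,yes,101.00,yes,102.00,yes,104.00,yes,104.00
ID06,100.00,yes,102.40,yes,103.00,yes,102.00,yes,105.40
ID07,100.00,yes,105.00,yes,104.00,yes,102.50,yes,103.00
ID08,180.00,no,,yes,183.00,yes,182.00,yes,185.00
ID09,158.00,no,,yes,161.00,yes,159.00,yes,164.00
ID10,216.00,yes,186.00,yes,224.00,yes,218.00,yes,227.00
ID11,290.00,yes,224.00,yes,301.00,yes,292.00,yes,305.00
ID12,290.00,yes,195.00,yes,296.00,yes,294.00,yes,299.00
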