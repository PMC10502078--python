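food,n_snps,rsids
dark_bread,10,rs1514175;rs543874;rs2867125;rs13107325;rs206936;rs7127684;rs7138803;rs1421085;rs571312;rs3810291
biscuits_and_cookies,7,rs543874;rs11676272;rs3817334;rs7138803;rs10134820;rs2241423;rs571312
sugary_juice_drink,7,rs2815752;rs1514175;rs543874;rs2867125;rs10938397;rs7138803;rs1421085
sweets_and_chocolate,10,rs2815752;rs543874;rs2867125;rs11676272;rs10938397;rs2112347;rs10134820;rs1421085;rs571312;rs2287019
pizza,11,rs2815752;rs543874;rs2867125;rs11676272;rs887912;rs10938397;rs2112347;rs7127684;rs7138803;rs1421085;rs3810291
hamburger_and_hotdog,7,rs2815752;rs543874;rs2867125;rs11676272;rs10938397;rs10134820;rs1421085
milk_and_sourmilk,12,rs1514175;rs543874;rs11676272;rs10938397;rs206936;rs2030323;rs3817334;rs7138803;rs2241423;rs12444979;rs1421085;rs571312
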