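species,metric,mean,sd,n,mounting_medium
B. nana,mean_width,20.54,0.92,107,silicone
B. humilis,mean_width,22.14,0.99,104,silicone
B. pendula,mean_width,22.41,0.88,339,silicone
B. pubescens,mean_width,25.46,1.11,66,silicone
B. nana,area,311.7,26.4,107,silicone
B. humilis,area,359.9,33.9,104,silicone
B. pendula,area,372.0,29.0,339,silicone
B. pubescens,area,478.6,39.7,66,silicone
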