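# name	hex
white	#FFFFFF
blue	#0072BC
green	#00A651
yellow	#FFD400
orange	#F47920
pink	#F69EA1
purple	#A54399
lightblue	#8FCCE9
brown	#A17A4D
red	#ED1C24
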