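#coords=1-based-inclusive
#start	end	scope
302	315	all
513	525	all
568	573	all
956	965	all
3105	3109	all
5895	5899	all
8270	8289	all
16180	16195	indel
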