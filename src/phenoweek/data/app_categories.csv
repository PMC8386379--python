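app,category
chatterly,social
snapgram,social
friendfeed,social
mindfulpath,wellness
calmspace,wellness
stepstracker,wellness
textly,communication
mailhub,communication
callhub,communication
newsreader,other
gamebox,other
mapsgo,other
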