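token,score
good,0.6
great,0.8
happy,0.9
hopeful,0.8
calm,0.6
relaxed,0.7
proud,0.8
excited,0.8
grateful,0.9
love,1.0
loved,0.9
enjoy,0.8
enjoyed,0.8
fun,0.7
wonderful,0.9
amazing,0.9
better,0.5
best,0.8
fine,0.3
content,0.5
peaceful,0.7
cheerful,0.8
energetic,0.7
motivated,0.7
optimistic,0.8
pleasant,0.6
friendly,0.6
laugh,0.7
laughed,0.7
smile,0.7
smiled,0.7
rested,0.6
refreshed,0.7
productive,0.6
accomplished,0.8
confident,0.7
warm,0.5
bright,0.5
nice,0.5
easier,0.4
sad,-0.8
down,-0.5
tired,-0.4
exhausted,-0.7
anxious,-0.7
worried,-0.6
stressed,-0.7
lonely,-0.8
alone,-0.5
empty,-0.7
hopeless,-1.0
worthless,-1.0
guilty,-0.7
irritable,-0.6
angry,-0.7
upset,-0.6
cry,-0.7
cried,-0.7
crying,-0.8
numb,-0.6
overwhelmed,-0.7
afraid,-0.7
scared,-0.7
restless,-0.5
sleepless,-0.6
awful,-0.9
terrible,-0.9
horrible,-0.9
worse,-0.6
worst,-0.8
bad,-0.6
depressed,-0.9
miserable,-0.9
gloomy,-0.7
dark,-0.4
heavy,-0.4
struggle,-0.6
struggled,-0.6
pain,-0.7
hurt,-0.6
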