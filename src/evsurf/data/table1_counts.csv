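# Recapture of single large EVs by the laser trap at the end of recording,
# split by compartment of adhesion and motility (published counts).
compartment,motion,recaptured,total
neurite,moving,15,15
neurite,not_moving,12,24
soma,moving,10,10
soma,not_moving,4,15
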