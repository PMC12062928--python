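pattern	category
attempt play bite	offensive
peek a boo	offensive
play bite	offensive
play brusque rush	offensive
play chase	offensive
play climb or stand on another	offensive
play drag	offensive
play eye cover	offensive
play jump	offensive
play jump (alone)	neutral
play kick	offensive
play pull	offensive
play push	offensive
play retrieve	offensive
play slap	offensive
play stamp	offensive
play tug-of-war	offensive
rough and tumble	offensive
play flee	defensive
play shelter	defensive
play wriggle	defensive
acrobatic play	neutral
airplane	neutral
pirouetting	neutral
play carry	neutral
play give me five	neutral
play grab	neutral
play manipulation	neutral
play moon walk	neutral
play pat	neutral
play piggy back ride	neutral
play roll	neutral
play shake the rope	neutral
play slide down	neutral
play turn around	neutral
play walk	neutral
somersault	neutral
tickle	neutral
play invitation	neutral
full play face	neutral
play face	neutral
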