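feature,dimension
negate,Language structure
article,Language structure
posemo,Affect
negemo,Affect
family,Social processes
social,Social processes
insight,Cognition
tentat,Cognition
see,Perception
hear,Perception
nonflu,Conversational dynamics
assent,Conversational dynamics
focuspast,Time orientation
focusfuture,Time orientation
health,Physical states
body,Physical states
risk,Drives
reward,Drives
home,Lifestyle
work,Lifestyle
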