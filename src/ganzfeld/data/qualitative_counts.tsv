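table	category	experiment	count
time_perception	Shorter than 25 min.	1	5
time_perception	Shorter than 25 min.	2	16
time_perception	Shorter than 25 min.	3	29
time_perception	Lack of time awareness	1	7
time_perception	Lack of time awareness	2	3
time_perception	Lack of time awareness	3	10
depth_perception	Red closer	3	19
depth_perception	Blue further	3	24
depth_perception	Loss of depth perception	1	4
depth_perception	Loss of depth perception	2	26
depth_perception	Loss of depth perception	3	50
bodily_sensations	Imbalance	1	2
bodily_sensations	Imbalance	2	5
bodily_sensations	Imbalance	3	6
bodily_sensations	Lightness, Floating, Weight	1	1
bodily_sensations	Lightness, Floating, Weight	2	10
bodily_sensations	Lightness, Floating, Weight	3	15
bodily_sensations	Externally directed	3	23
bodily_sensations	Inward directed	3	23
bodily_sensations	Eye-related	1	13
bodily_sensations	Eye-related	2	9
bodily_sensations	Eye-related	3	19
bodily_sensations	Posture	1	9
bodily_sensations	Posture	2	8
bodily_sensations	Posture	3	9
bodily_sensations	Tiredness	1	19
bodily_sensations	Tiredness	2	12
bodily_sensations	Tiredness	3	13
bodily_sensations	Relaxation	1	9
bodily_sensations	Relaxation	2	15
bodily_sensations	Relaxation	3	17
bodily_sensations	Tension and Shaking	1	10
bodily_sensations	Tension and Shaking	2	8
bodily_sensations	Tension and Shaking	3	11
bodily_sensations	Temperature	1	3
bodily_sensations	Temperature	2	7
bodily_sensations	Temperature	3	10
bodily_sensations	Tingling, Vibrating	1	2
bodily_sensations	Tingling, Vibrating	2	2
bodily_sensations	Tingling, Vibrating	3	5
bodily_sensations	Loss of Reality	1	5
bodily_sensations	Loss of Reality	2	7
bodily_sensations	Loss of Reality	3	11
bodily_sensations	Unpleasantness	2	4
bodily_sensations	Unpleasantness	3	6
bodily_sensations	Need to Move	3	8
feelings_emotions	Relaxing	1	13
feelings_emotions	Relaxing	2	19
feelings_emotions	Relaxing	3	45
feelings_emotions	Intense	1	8
feelings_emotions	Intense	2	4
feelings_emotions	Intense	3	14
feelings_emotions	Meditative and Contemplative Experiences	1	3
feelings_emotions	Meditative and Contemplative Experiences	2	4
feelings_emotions	Meditative and Contemplative Experiences	3	12
feelings_emotions	Altered Awareness	1	3
feelings_emotions	Altered Awareness	2	8
feelings_emotions	Altered Awareness	3	19
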