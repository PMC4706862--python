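student_id	rank	name
S_46	1	Human
S_46	2	Monkey
S_46	3	Donkey
S_46	4	Bird
S_46	5	Cow
S_46	6	Camel
S_46	7	Frog
S_46	8	Turtle
S_46	9	Mouse
S_46	10	Cat
S_47	1	Cat
S_47	2	Dog
S_47	3	Tree
S_47	4	Eagle
S_47	5	Dolphin
S_47	6	Pigeon
S_47	7	Lion
S_47	8	Whale
S_47	9	Daisy
S_47	10	Snowdrop
S_48	1	Lion
S_48	2	Human
S_48	3	Plant
S_48	4	Panda
S_48	5	Snake
S_48	6	Dolphin
S_48	7	Zebra
S_48	8	Penguin
S_48	9	Bear
S_48	10	Wolf
S_49	1	Human
S_49	2	Plant
S_49	3	Dog
S_49	4	Algae
S_49	5	Bacterium
S_49	6	Mushroom
S_49	7	Bird
S_49	8	Lion
S_49	9	Leopard
S_49	10	Cat
S_50	1	Dolphin
S_50	2	Dog
S_50	3	Human
S_50	4	Daisy
S_50	5	Rose
S_50	6	Ox
S_50	7	Bear
S_50	8	Whale
S_50	9	Monkey
S_50	10	Chrysanthemum
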