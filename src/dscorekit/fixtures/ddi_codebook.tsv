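item	debut	domain	label
ddicmm029	1	Communication	Reacts when spoken to
ddifmd001	1	Fine motor	Eyes fixate
ddigmd052	1	Gross motor	Moves arms equally well
ddigmd053	1	Gross motor	Moves legs equally well
ddigmd056	1	Gross motor	Lifts chin off table for a moment
ddicmm030	2	Communication	Smiles in response (M; can ask parents)
ddifmd002	2	Fine motor	Follows with eyes and head 30d < 0 > 30d
ddicmm031	3	Communication	vocalizes in response
ddifmd003	3	Fine motor	Hands open occasionally
ddifmm004	3	Fine motor	Watches own hands
ddigmd054	3	Gross motor	Stays suspended when lifted under the armpits
ddigmd057	3	Gross motor	Lifts head to 45 degrees on prone position
ddicmd116	6	Communication	Turn head to sound
ddifmd005	6	Fine motor	Plays with hands in midline
ddigmd006	6	Gross motor	Grasps object within reach
ddigmd055	6	Gross motor	No head lag if pulled to sitting
ddigmd058	6	Gross motor	Looks around to side with angle face-table 90
ddigmd059	6	Gross motor	Flexes or stomps legs while being swung
ddicmm033	9	Communication	Says dada, baba, gaga
ddifmd007	9	Fine motor	Passes cube from hand to hand
ddifmd008	9	Fine motor	Holds cube, grasps another one with other hand
ddifmm009	9	Fine motor	Plays with both feet
ddigmm060	9	Gross motor	Rolls over back to front
ddigmd061	9	Gross motor	Balances head well while sitting
ddigmd062	9	Gross motor	Sits on buttocks while legs stretched
ddicmm034	12	Communication	Babbles while playing
ddicmm036	12	Communication	Waves 'bye-bye' (M; can ask parents)
ddifmd010	12	Fine motor	Picks up pellet between thumb and index finger
ddigmd063	12	Gross motor	Sits in stable position without support
ddigmm064	12	Gross motor	Crawls forward, abdomen on the floor
ddigmm065	12	Gross motor	Pulls up to standing position
ddicmm037	15	Communication	Uses two words with comprehension
ddicmd136	15	Communication	Reacts to verbal request (M; can ask parents)
ddifmd011	15	Fine motor	Puts cube in and out of a box
ddifmm012	15	Fine motor	Plays 'give and take' (M; can ask parents)
ddigmm066	15	Gross motor	Crawls, abdomen off the floor (M; can ask parents)
ddigmm067	15	Gross motor	Walks while holding onto play-pen or furniture
ddicmm039	18	Communication	Says three 'words'
ddicmd141	18	Communication	Identifies two named objects
ddifmd013	18	Fine motor	Tower of 2 cubes
ddifmm014	18	Fine motor	Explores environment energetically (M; can ask parents)
ddigmd068	18	Gross motor	Walks alone
ddigmd069	18	Gross motor	Throws ball without falling
ddicmm041	24	Communication	Says sentences with 2 words
ddicmd148	24	Communication	Understands 'play' orders
ddifmd015	24	Fine motor	Builds tower of 3 cubes
ddifmm016	24	Fine motor	Imitates everyday activities (M; can ask parents)
ddigmd070	24	Gross motor	Squats or bends to pick things up
ddigmd146	24	Gross motor	Drinks from cup (M; can ask parents)
ddigmd168	24	Gross motor	Walks well
ddicmm043	30	Communication	Refers to self using 'me' or 'I' (M; can ask parents)
ddicmd044	30	Communication	Points at 5 pictures in the book
ddifmd017	30	Fine motor	Tower of 6 cubes
ddifmd018	30	Fine motor	Places round block in board
ddifmm019	30	Fine motor	Takes off shoes and socks (M; can ask parents)
ddifmd154	30	Fine motor	Eats with spoon without help (M; can ask parents)
ddigmd071	30	Gross motor	Kicks ball
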