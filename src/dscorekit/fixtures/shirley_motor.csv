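name,sex,stepping,standing,walking_with_help,walking_alone
Martin,boy,15,,21,50
Carol,girl,15,19,37,50
Max,boy,14,,25,54
Virginia Ruth,girl,,21,41,54
Sibyl,girl,,22,37,58
David,boy,19,27,34,60
James D.,boy,19,30,45,60
Harvey,boy,14,27,42,62
Winnifred,girl,15,30,41,62
Quentin,boy,15,23,38,64
Maurice,boy,18,23,45,66
Judy,girl,18,29,45,66
Irene May,girl,19,34,45,66
Peter,boy,15,29,49,66
Walley,boy,18,33,54,68
Fred,boy,15,32,46,70
Donovan,boy,,23,50,70
Patricia,girl,15,30,45,70
Torey,boy,,21,72,74
Larry,boy,13,41,54,76
Doris,girl,,23,44,
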