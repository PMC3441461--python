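RUUUUUU
RUUUUUL
RUUUUUR
RUUUULU
RUUUULD
RUUUULL
RUUUURU
RUUUURD
RUUUURR
RUUULUU
RUUULUL
RUUULUR
RUUULDD
RUUULDL
RUUULLU
RUUULLD
RUUULLL
RUUURUU
RUUURUL
RUUURUR
RUUURDD
RUUURDR
RUUURRU
RUUURRD
RUUURRR
RUULUUU
RUULUUL
RUULUUR
RUULULU
RUULULD
RUULULL
RUULURU
RUULURR
RUULDLU
RUULDLD
RUULDLL
RUULLUU
RUULLUL
RUULLUR
RUULLDD
RUULLDL
RUULLDR
RUULLLU
RUULLLD
RUULLLL
RUURUUU
RUURUUL
RUURUUR
RUURULU
RUURULL
RUURURU
RUURURD
RUURURR
RUURDDD
RUURDDR
RUURDRU
RUURDRD
RUURDRR
RUURRUU
RUURRUL
RUURRUR
RUURRDD
RUURRDL
RUURRDR
RUURRRU
RUURRRD
RUURRRR
RULUUUU
RULUUUL
RULUUUR
RULUULU
RULUULD
RULUULL
RULUURU
RULUURD
RULUURR
RULULUU
RULULUL
RULULUR
RULULDD
RULULDL
RULULLU
RULULLD
RULULLL
RULURUU
RULURUL
RULURUR
RULURRU
RULURRD
RULURRR
RULLUUU
RULLUUL
RULLUUR
RULLULU
RULLULD
RULLULL
RULLURU
RULLURR
RULLDDD
RULLDDL
RULLDDR
RULLDLU
RULLDLD
RULLDLL
RULLLUU
RULLLUL
RULLLUR
RULLLDD
RULLLDL
RULLLDR
RULLLLU
RULLLLD
RULLLLL
RURUUUU
RURUUUL
RURUUUR
RURUULU
RURUULD
RURUULL
RURUURU
RURUURD
RURUURR
RURULUU
RURULUL
RURULUR
RURULLU
RURULLD
RURULLL
RURURUU
RURURUL
RURURUR
RURURDD
RURURDR
RURURRU
RURURRD
RURURRR
RURDDDD
RURDDDL
RURDDDR
RURDDLD
RURDDLL
RURDDRU
RURDDRD
RURDDRR
RURDRUU
RURDRUR
RURDRDD
RURDRDL
RURDRDR
RURDRRU
RURDRRD
RURDRRR
RURRUUU
RURRUUL
RURRUUR
RURRULU
RURRULL
RURRURU
RURRURD
RURRURR
RURRDDD
RURRDDL
RURRDDR
RURRDLD
RURRDRU
RURRDRD
RURRDRR
RURRRUU
RURRRUL
RURRRUR
RURRRDD
RURRRDL
RURRRDR
RURRRRU
RURRRRD
RURRRRR
RRUUUUU
RRUUUUL
RRUUUUR
RRUUULU
RRUUULD
RRUUULL
RRUUURU
RRUUURD
RRUUURR
RRUULUU
RRUULUL
RRUULUR
RRUULDL
RRUULLU
RRUULLD
RRUULLL
RRUURUU
RRUURUL
RRUURUR
RRUURDD
RRUURDR
RRUURRU
RRUURRD
RRUURRR
RRULUUU
RRULUUL
RRULUUR
RRULULU
RRULULD
RRULULL
RRULURU
RRULURR
RRULLUU
RRULLUL
RRULLUR
RRULLLU
RRULLLD
RRULLLL
RRURUUU
RRURUUL
RRURUUR
RRURULU
RRURULL
RRURURU
RRURURD
RRURURR
RRURDDD
RRURDDL
RRURDDR
RRURDRU
RRURDRD
RRURDRR
RRURRUU
RRURRUL
RRURRUR
RRURRDD
RRURRDL
RRURRDR
RRURRRU
RRURRRD
RRURRRR
RRRUUUU
RRRUUUL
RRRUUUR
RRRUULU
RRRUULD
RRRUULL
RRRUURU
RRRUURD
RRRUURR
RRRULUU
RRRULUL
RRRULUR
RRRULLU
RRRULLL
RRRURUU
RRRURUL
RRRURUR
RRRURDD
RRRURDR
RRRURRU
RRRURRD
RRRURRR
RRRRUUU
RRRRUUL
RRRRUUR
RRRRULU
RRRRULL
RRRRURU
RRRRURD
RRRRURR
RRRRRUU
RRRRRUL
RRRRRUR
RRRRRRU
RRRRRRR
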