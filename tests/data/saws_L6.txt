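RUUUU
RUUUL
RUUUR
RUULU
RUULD
RUULL
RUURU
RUURD
RUURR
RULUU
RULUL
RULUR
RULLU
RULLD
RULLL
RURUU
RURUL
RURUR
RURDD
RURDR
RURRU
RURRD
RURRR
RRUUU
RRUUL
RRUUR
RRULU
RRULL
RRURU
RRURD
RRURR
RRRUU
RRRUL
RRRUR
RRRRU
RRRRR
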