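ID SYN_CREB_LIKE
NA SYN_CREB_LIKE
P0      A      C      G      T
01      1      1      1     17  T
02      1      1     17      1  G
03     17      1      1      1  A
04      1     17      1      1  C
05      1      1     17      1  G
06      1      1      1     17  T
07      1     17      1      1  C
08     17      1      1      1  A
//
ID SYN_NFKB_LIKE
NA SYN_NFKB_LIKE
P0      A      C      G      T
01      0      0     20      0  G
02      0      0     20      0  G
03      0      0     20      0  G
04     14      2      2      2  A
05      5      9      3      3  C
06      3      3      3     11  T
07      2      2      2     14  T
08      0      0      0     20  T
09      0     20      0      0  C
10      0     20      0      0  C
//
ID SYN_ISRE_LIKE
NA SYN_ISRE_LIKE
P0      A      C      G      T
01      0      0     20      0  G
02     20      0      0      0  A
03     20      0      0      0  A
04     20      0      0      0  A
05      0     20      0      0  C
06      0      0      0     20  T
07      0      0     20      0  G
08     20      0      0      0  A
09     20      0      0      0  A
10     20      0      0      0  A
11      0     20      0      0  C
12      0      0      0     20  T
//
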