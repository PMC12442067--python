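benzene
0 0 0

naphthalene
0 0 0
1 0 0

anthracene
0 0 0
1 0 0
2 0 0

phenanthrene
0 0 0
1 0 0
1 1 0

triphenylene
0 0 0
1 0 0
-1 1 0
0 -1 0

benzo[c]phenanthrene
1 0 0
0 1 0
-1 1 0
-1 0 0

pyrene
0 0 0
1 0 0
0 1 0
1 -1 0

a_s1
0 0 0
1 0 0
0 1 0
1 -1 0
1 -2 0

aa_s1
0 0 0
1 0 0
0 1 0
1 -1 0
0 2 0
1 -2 0

aa_s2
0 0 0
1 0 0
0 1 0
1 -1 0
0 2 0
2 -2 0

aab_s1
0 0 0
1 0 0
0 1 0
1 -1 0
0 2 0
2 -2 0
2 0 0

aab_s2
0 0 0
1 0 0
0 1 0
1 -1 0
0 2 0
1 -2 0
2 0 0

aab_s3
0 0 0
1 0 0
0 1 0
1 -1 0
0 2 0
2 -2 0
-1 0 0

aabb_s1
0 0 0
1 0 0
0 1 0
1 -1 0
0 2 0
1 -2 0
-1 0 0
2 0 0

aabb_s2
0 0 0
1 0 0
0 1 0
1 -1 0
0 2 0
2 -2 0
-1 0 0
2 0 0

ab_s1
0 0 0
1 0 0
0 1 0
1 -1 0
1 -2 0
-1 0 0

ab_s2
0 0 0
1 0 0
0 1 0
1 -1 0
1 -2 0
2 0 0

abb_s1
0 0 0
1 0 0
0 1 0
1 -1 0
1 -2 0
-1 0 0
2 0 0

b_s1
0 0 0
1 0 0
0 1 0
1 -1 0
2 0 0

bb_s1
0 0 0
1 0 0
0 1 0
1 -1 0
-1 0 0
2 0 0
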