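subject,visit,y,base,trt,age
1,1,5,11,0,31
1,2,3,11,0,31
1,3,3,11,0,31
1,4,3,11,0,31
2,1,3,11,0,30
2,2,5,11,0,30
2,3,3,11,0,30
2,4,3,11,0,30
3,1,2,6,0,25
3,2,4,6,0,25
3,3,0,6,0,25
3,4,5,6,0,25
4,1,4,8,0,36
4,2,4,8,0,36
4,3,1,8,0,36
4,4,4,8,0,36
5,1,7,66,0,22
5,2,18,66,0,22
5,3,9,66,0,22
5,4,21,66,0,22
6,1,5,27,0,29
6,2,2,27,0,29
6,3,8,27,0,29
6,4,7,27,0,29
7,1,6,12,0,31
7,2,4,12,0,31
7,3,0,12,0,31
7,4,2,12,0,31
8,1,40,52,0,42
8,2,20,52,0,42
8,3,21,52,0,42
8,4,12,52,0,42
9,1,5,23,0,37
9,2,6,23,0,37
9,3,6,23,0,37
9,4,5,23,0,37
10,1,14,10,0,28
10,2,13,10,0,28
10,3,6,10,0,28
10,4,0,10,0,28
11,1,26,52,0,36
11,2,12,52,0,36
11,3,6,52,0,36
11,4,22,52,0,36
12,1,12,33,0,24
12,2,6,33,0,24
12,3,8,33,0,24
12,4,4,33,0,24
13,1,4,18,0,23
13,2,4,18,0,23
13,3,6,18,0,23
13,4,2,18,0,23
14,1,7,42,0,36
14,2,9,42,0,36
14,3,12,42,0,36
14,4,14,42,0,36
15,1,16,87,0,26
15,2,24,87,0,26
15,3,10,87,0,26
15,4,9,87,0,26
16,1,11,50,0,26
16,2,0,50,0,26
16,3,0,50,0,26
16,4,5,50,0,26
17,1,0,18,0,28
17,2,0,18,0,28
17,3,3,18,0,28
17,4,3,18,0,28
18,1,37,111,0,31
18,2,29,111,0,31
18,3,28,111,0,31
18,4,29,111,0,31
19,1,3,18,0,32
19,2,5,18,0,32
19,3,2,18,0,32
19,4,5,18,0,32
20,1,3,20,0,21
20,2,0,20,0,21
20,3,6,20,0,21
20,4,7,20,0,21
21,1,3,12,0,29
21,2,4,12,0,29
21,3,3,12,0,29
21,4,4,12,0,29
22,1,3,9,0,21
22,2,4,9,0,21
22,3,3,9,0,21
22,4,4,9,0,21
23,1,2,17,0,32
23,2,3,17,0,32
23,3,3,17,0,32
23,4,5,17,0,32
24,1,8,28,0,25
24,2,12,28,0,25
24,3,2,28,0,25
24,4,8,28,0,25
25,1,18,55,0,30
25,2,24,55,0,30
25,3,76,55,0,30
25,4,25,55,0,30
26,1,2,9,0,40
26,2,1,9,0,40
26,3,2,9,0,40
26,4,1,9,0,40
27,1,3,10,0,19
27,2,1,10,0,19
27,3,4,10,0,19
27,4,2,10,0,19
28,1,13,47,0,22
28,2,15,47,0,22
28,3,13,47,0,22
28,4,12,47,0,22
29,1,11,76,1,18
29,2,14,76,1,18
29,3,9,76,1,18
29,4,8,76,1,18
30,1,8,38,1,32
30,2,7,38,1,32
30,3,9,38,1,32
30,4,4,38,1,32
31,1,0,19,1,20
31,2,4,19,1,20
31,3,3,19,1,20
31,4,0,19,1,20
32,1,3,10,1,30
32,2,6,10,1,30
32,3,1,10,1,30
32,4,3,10,1,30
33,1,2,19,1,18
33,2,6,19,1,18
33,3,7,19,1,18
33,4,4,19,1,18
34,1,4,24,1,24
34,2,3,24,1,24
34,3,1,24,1,24
34,4,3,24,1,24
35,1,22,31,1,30
35,2,17,31,1,30
35,3,19,31,1,30
35,4,16,31,1,30
36,1,5,14,1,35
36,2,4,14,1,35
36,3,7,14,1,35
36,4,4,14,1,35
37,1,2,11,1,27
37,2,4,11,1,27
37,3,0,11,1,27
37,4,4,11,1,27
38,1,3,67,1,20
38,2,7,67,1,20
38,3,7,67,1,20
38,4,7,67,1,20
39,1,4,41,1,22
39,2,18,41,1,22
39,3,2,41,1,22
39,4,5,41,1,22
40,1,2,7,1,28
40,2,1,7,1,28
40,3,1,7,1,28
40,4,0,7,1,28
41,1,0,22,1,23
41,2,2,22,1,23
41,3,4,22,1,23
41,4,0,22,1,23
42,1,5,13,1,40
42,2,4,13,1,40
42,3,0,13,1,40
42,4,3,13,1,40
43,1,11,46,1,33
43,2,14,46,1,33
43,3,25,46,1,33
43,4,15,46,1,33
44,1,10,36,1,21
44,2,5,36,1,21
44,3,3,36,1,21
44,4,8,36,1,21
45,1,19,38,1,35
45,2,7,38,1,35
45,3,6,38,1,35
45,4,7,38,1,35
46,1,1,7,1,25
46,2,1,7,1,25
46,3,2,7,1,25
46,4,3,7,1,25
47,1,6,36,1,26
47,2,10,36,1,26
47,3,8,36,1,26
47,4,8,36,1,26
48,1,2,11,1,25
48,2,1,11,1,25
48,3,0,11,1,25
48,4,0,11,1,25
49,1,102,151,1,22
49,2,65,151,1,22
49,3,72,151,1,22
49,4,63,151,1,22
50,1,4,22,1,32
50,2,3,22,1,32
50,3,2,22,1,32
50,4,4,22,1,32
51,1,8,41,1,25
51,2,6,41,1,25
51,3,5,41,1,25
51,4,7,41,1,25
52,1,1,32,1,35
52,2,3,32,1,35
52,3,1,32,1,35
52,4,5,32,1,35
53,1,18,56,1,21
53,2,11,56,1,21
53,3,28,56,1,21
53,4,13,56,1,21
54,1,6,24,1,41
54,2,3,24,1,41
54,3,4,24,1,41
54,4,0,24,1,41
55,1,3,16,1,32
55,2,5,16,1,32
55,3,4,16,1,32
55,4,3,16,1,32
56,1,1,22,1,26
56,2,23,22,1,26
56,3,19,22,1,26
56,4,8,22,1,26
57,1,2,25,1,21
57,2,3,25,1,21
57,3,0,25,1,21
57,4,1,25,1,21
58,1,0,13,1,36
58,2,0,13,1,36
58,3,0,13,1,36
58,4,0,13,1,36
59,1,1,12,1,37
59,2,4,12,1,37
59,3,3,12,1,37
59,4,2,12,1,37
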