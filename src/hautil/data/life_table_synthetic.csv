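age,sex,ex
21,female,55.4
22,female,54.6
23,female,53.8
24,female,53.0
25,female,52.2
26,female,51.4
27,female,50.6
28,female,49.8
29,female,49.0
30,female,48.2
31,female,47.4
32,female,46.6
33,female,45.8
34,female,45.0
35,female,44.2
36,female,43.4
37,female,42.6
38,female,41.8
39,female,41.0
40,female,40.2
41,female,39.4
42,female,38.6
43,female,37.8
44,female,37.0
45,female,36.2
46,female,35.4
47,female,34.6
48,female,33.8
49,female,33.0
50,female,32.2
51,female,31.4
52,female,30.6
53,female,29.8
54,female,29.0
55,female,28.2
56,female,27.4
57,female,26.6
58,female,25.8
59,female,25.0
60,female,24.2
61,female,23.4
62,female,22.6
63,female,21.8
64,female,21.0
65,female,20.2
66,female,19.4
67,female,18.6
68,female,17.8
69,female,17.0
70,female,16.2
71,female,15.4
72,female,14.6
73,female,13.8
74,female,13.0
75,female,12.2
76,female,11.4
77,female,10.6
78,female,9.8
79,female,9.0
80,female,8.2
21,male,54.6
22,male,53.8
23,male,53.0
24,male,52.2
25,male,51.4
26,male,50.6
27,male,49.8
28,male,49.0
29,male,48.2
30,male,47.4
31,male,46.6
32,male,45.8
33,male,45.0
34,male,44.2
35,male,43.4
36,male,42.6
37,male,41.8
38,male,41.0
39,male,40.2
40,male,39.4
41,male,38.6
42,male,37.8
43,male,37.0
44,male,36.2
45,male,35.4
46,male,34.6
47,male,33.8
48,male,33.0
49,male,32.2
50,male,31.4
51,male,30.6
52,male,29.8
53,male,29.0
54,male,28.2
55,male,27.4
56,male,26.6
57,male,25.8
58,male,25.0
59,male,24.2
60,male,23.4
61,male,22.6
62,male,21.8
63,male,21.0
64,male,20.2
65,male,19.4
66,male,18.6
67,male,17.8
68,male,17.0
69,male,16.2
70,male,15.4
71,male,14.6
72,male,13.8
73,male,13.0
74,male,12.2
75,male,11.4
76,male,10.6
77,male,9.8
78,male,9.0
79,male,8.2
80,male,7.4
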