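# nanosorb topology; atom indices are 1-based
[bonds] 112
1 35
1 36
1 37
2 33
2 34
2 38
3 36
3 39
3 51
4 39
4 40
4 48
4 49
5 33
5 35
5 39
5 41
6 39
6 42
6 44
6 45
7 33
7 43
7 48
8 43
8 44
8 51
8 52
9 36
9 38
9 43
9 45
10 40
10 41
10 43
10 46
11 49
11 50
11 51
12 47
12 48
12 52
13 37
13 50
13 53
14 34
14 35
14 53
14 54
15 47
15 49
15 53
15 55
16 53
16 56
16 58
16 59
17 34
17 47
17 57
18 37
18 38
18 57
18 58
19 50
19 52
19 57
19 59
20 54
20 55
20 57
20 60
21 35
21 45
21 58
21 61
22 41
22 42
22 61
23 54
23 56
23 61
24 38
24 41
24 54
24 62
25 45
25 46
25 62
26 58
26 60
26 62
27 44
27 49
27 59
27 63
28 55
28 56
28 63
29 40
29 42
29 63
30 40
30 52
30 55
30 64
31 59
31 60
31 64
32 44
32 46
32 64
[angles] 288
35 1 36
35 1 37
36 1 37
33 2 34
33 2 38
34 2 38
36 3 39
36 3 51
39 3 51
39 4 40
39 4 48
39 4 49
40 4 48
40 4 49
48 4 49
33 5 35
33 5 39
33 5 41
35 5 39
35 5 41
39 5 41
39 6 42
39 6 44
39 6 45
42 6 44
42 6 45
44 6 45
33 7 43
33 7 48
43 7 48
43 8 44
43 8 51
43 8 52
44 8 51
44 8 52
51 8 52
36 9 38
36 9 43
36 9 45
38 9 43
38 9 45
43 9 45
40 10 41
40 10 43
40 10 46
41 10 43
41 10 46
43 10 46
49 11 50
49 11 51
50 11 51
47 12 48
47 12 52
48 12 52
37 13 50
37 13 53
50 13 53
34 14 35
34 14 53
34 14 54
35 14 53
35 14 54
53 14 54
47 15 49
47 15 53
47 15 55
49 15 53
49 15 55
53 15 55
53 16 56
53 16 58
53 16 59
56 16 58
56 16 59
58 16 59
34 17 47
34 17 57
47 17 57
37 18 38
37 18 57
37 18 58
38 18 57
38 18 58
57 18 58
50 19 52
50 19 57
50 19 59
52 19 57
52 19 59
57 19 59
54 20 55
54 20 57
54 20 60
55 20 57
55 20 60
57 20 60
35 21 45
35 21 58
35 21 61
45 21 58
45 21 61
58 21 61
41 22 42
41 22 61
42 22 61
54 23 56
54 23 61
56 23 61
38 24 41
38 24 54
38 24 62
41 24 54
41 24 62
54 24 62
45 25 46
45 25 62
46 25 62
58 26 60
58 26 62
60 26 62
44 27 49
44 27 59
44 27 63
49 27 59
49 27 63
59 27 63
55 28 56
55 28 63
56 28 63
40 29 42
40 29 63
42 29 63
40 30 52
40 30 55
40 30 64
52 30 55
52 30 64
55 30 64
59 31 60
59 31 64
60 31 64
44 32 46
44 32 64
46 32 64
2 33 5
2 33 7
5 33 7
2 34 14
2 34 17
14 34 17
1 35 5
1 35 14
1 35 21
5 35 14
5 35 21
14 35 21
1 36 3
1 36 9
3 36 9
1 37 13
1 37 18
13 37 18
2 38 9
2 38 18
2 38 24
9 38 18
9 38 24
18 38 24
3 39 4
3 39 5
3 39 6
4 39 5
4 39 6
5 39 6
4 40 10
4 40 29
4 40 30
10 40 29
10 40 30
29 40 30
5 41 10
5 41 22
5 41 24
10 41 22
10 41 24
22 41 24
6 42 22
6 42 29
22 42 29
7 43 8
7 43 9
7 43 10
8 43 9
8 43 10
9 43 10
6 44 8
6 44 27
6 44 32
8 44 27
8 44 32
27 44 32
6 45 9
6 45 21
6 45 25
9 45 21
9 45 25
21 45 25
10 46 25
10 46 32
25 46 32
12 47 15
12 47 17
15 47 17
4 48 7
4 48 12
7 48 12
4 49 11
4 49 15
4 49 27
11 49 15
11 49 27
15 49 27
11 50 13
11 50 19
13 50 19
3 51 8
3 51 11
8 51 11
8 52 12
8 52 19
8 52 30
12 52 19
12 52 30
19 52 30
13 53 14
13 53 15
13 53 16
14 53 15
14 53 16
15 53 16
14 54 20
14 54 23
14 54 24
20 54 23
20 54 24
23 54 24
15 55 20
15 55 28
15 55 30
20 55 28
20 55 30
28 55 30
16 56 23
16 56 28
23 56 28
17 57 18
17 57 19
17 57 20
18 57 19
18 57 20
19 57 20
16 58 18
16 58 21
16 58 26
18 58 21
18 58 26
21 58 26
16 59 19
16 59 27
16 59 31
19 59 27
19 59 31
27 59 31
20 60 26
20 60 31
26 60 31
21 61 22
21 61 23
22 61 23
24 62 25
24 62 26
25 62 26
27 63 28
27 63 29
28 63 29
30 64 31
30 64 32
31 64 32
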