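>site1
TTGACAATTGTCAA
>site2
TTGACTATAGTCAA
>site3
TTGACAATTGTCGA
>site4
TTTACAGTTGTCAA
>site5
TTGACGATAGTCAA
>site6
CTGACAATTGTAAA
>site7
TTGACAGTTGGCAA
>site8
TTGATAATTGTCAA
>site9
TTGACATTTGTCAC
>site10
ATGACAATTGTCAA
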