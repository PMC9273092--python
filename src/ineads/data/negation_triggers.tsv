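trigger	direction
no	forward
not	forward
never	forward
without	forward
denies	forward
denied	forward
denying	forward
declines	forward
declined	forward
refuses	forward
refused	forward
unable	forward
cannot	forward
non	forward
negative	forward
absent	backward
unlikely	backward
doubtful	backward
unconfirmed	backward
resolved	backward
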