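kind	sequence	code_positions
C	FVKDVMSDEAQCTECKYNTHALPVVTTEGNPFYPDMMFEATVNVSSLAAKFIECVMQEATFELKGKFNKLKFRPQIECMRGAQKDLTKKR	
A	VDAQLRDKQNEMIFQSLIFGGLATSVDSSRQHDIRLNQWGWIHIWWGINDWNEKDKGECKQMLSGKMGILDWKPRPVYSDSSQNPVWYSNYQPDCRGWMWKQAVHCHHDMIISAPPGAAQ	12,25,37,49,58,66,75,84,96,105
T	NNWDAPPRSMHSCADVQGARNCKTPLQFPMFDGCCEKQVYHTGVP	
E	GMFLSCPPEMPSWMALHMYNMLPAPCWIGGPWRFFPCWCDFGISFNAAMASTMPFVHASGDPFRSPDALEVRDGGERPGI	
TE	GVFTKNDPYVRYWASNMMWTGSCPFWVVDLFRIPKTQNCTQDHWCSPHRCGYGYKHKPDYTKWQQVTATL	
RECEPTOR	DCRQVCSHMINSWDSTHQGETPKWWVGRKIAPCTQECQPTEVYYEDVYHMKYAEFWRYDQSEKWNVKMARCPAMFPFDEEIHDTMMMVRQYSCLLLHSMHAEMYPRACACEGWPCKCHGKFIWVNNIEFMWSTNYPTCRCKQHHCPETQN	
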